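"""Independent reference implementations used only to check the package.

These are deliberately written from textbook definitions (explicit means,
sample loops, eigenvalues) rather than through the package's own code
paths.
"""

import math

import numpy as np


def plv_brute(phase_a, phase_b) -> float:
    """Mean resultant length by an explicit cos/sin accumulation loop."""
    cs = sn = 0.0
    for x, y in zip(phase_a, phase_b):
        d = float(x) - float(y)
        cs += math.cos(d)
        sn += math.sin(d)
    n = len(phase_a)
    return math.sqrt(cs * cs + sn * sn) / n


def gg_epsilon_eigen(cov, contrast) -> float:
    """Greenhouse-Geisser epsilon via the eigenvalues of C'SC."""
    lam = np.linalg.eigvalsh(contrast.T @ np.asarray(cov) @ contrast)
    q = contrast.shape[1]
    denom = q * np.sum(lam**2)
    if denom <= 1e-30:
        return 1.0
    return float(np.clip(np.sum(lam) ** 2 / denom, 1.0 / q, 1.0))


def split_plot_anova_oracle(table):
    """Cell-means split-plot ANOVA for a balanced 2x(p x s) mixed design.

    ``table``: DataFrame with columns participant, group, posture,
    stimulus, value; equal group sizes, one value per cell. Returns a dict
    effect -> F computed from explicit marginal means, with the final
    error stratum obtained by subtraction from the total sum of squares.
    """
    groups = sorted(table["group"].unique())
    postures = sorted(table["posture"].unique())
    stimuli = sorted(table["stimulus"].unique())
    subjects = {g: sorted(table.loc[table.group == g, "participant"].unique())
                for g in groups}
    n_per = {g: len(subjects[g]) for g in groups}
    assert len(set(n_per.values())) == 1, "oracle expects equal group sizes"
    a, p, s = len(groups), len(postures), len(stimuli)
    n_sub = sum(n_per.values())
    w = p * s

    y = {}
    for r in table.itertuples():
        y[(r.group, r.participant, r.posture, r.stimulus)] = float(r.value)

    def mean(keys):
        vals = [y[k] for k in keys]
        return sum(vals) / len(vals)

    all_keys = list(y)
    gm = mean(all_keys)
    m_g = {g: mean([k for k in all_keys if k[0] == g]) for g in groups}
    m_gi = {(g, i): mean([k for k in all_keys if k[0] == g and k[1] == i])
            for g in groups for i in subjects[g]}
    m_p = {j: mean([k for k in all_keys if k[2] == j]) for j in postures}
    m_s = {k_: mean([k for k in all_keys if k[3] == k_]) for k_ in stimuli}
    m_gp = {(g, j): mean([k for k in all_keys if k[0] == g and k[2] == j])
            for g in groups for j in postures}
    m_gs = {(g, k_): mean([k for k in all_keys if k[0] == g and k[3] == k_])
            for g in groups for k_ in stimuli}
    m_ps = {(j, k_): mean([k for k in all_keys if k[2] == j and k[3] == k_])
            for j in postures for k_ in stimuli}
    m_gps = {(g, j, k_): mean([k for k in all_keys
                               if k[0] == g and k[2] == j and k[3] == k_])
             for g in groups for j in postures for k_ in stimuli}
    m_gip = {(g, i, j): mean([k for k in all_keys
                              if k[0] == g and k[1] == i and k[2] == j])
             for g in groups for i in subjects[g] for j in postures}
    m_gis = {(g, i, k_): mean([k for k in all_keys
                               if k[0] == g and k[1] == i and k[3] == k_])
             for g in groups for i in subjects[g] for k_ in stimuli}

    ss_g = w * sum(n_per[g] * (m_g[g] - gm) ** 2 for g in groups)
    ss_subj = w * sum((m_gi[(g, i)] - m_g[g]) ** 2
                      for g in groups for i in subjects[g])
    ss_p = n_sub * s * sum((m_p[j] - gm) ** 2 for j in postures)
    ss_gp = s * sum(n_per[g] * (m_gp[(g, j)] - m_g[g] - m_p[j] + gm) ** 2
                    for g in groups for j in postures)
    ss_perr = s * sum(
        (m_gip[(g, i, j)] - m_gi[(g, i)] - m_gp[(g, j)] + m_g[g]) ** 2
        for g in groups for i in subjects[g] for j in postures
    )
    ss_s = n_sub * p * sum((m_s[k_] - gm) ** 2 for k_ in stimuli)
    ss_gs = p * sum(n_per[g] * (m_gs[(g, k_)] - m_g[g] - m_s[k_] + gm) ** 2
                    for g in groups for k_ in stimuli)
    ss_serr = p * sum(
        (m_gis[(g, i, k_)] - m_gi[(g, i)] - m_gs[(g, k_)] + m_g[g]) ** 2
        for g in groups for i in subjects[g] for k_ in stimuli
    )
    ss_ps = n_sub * sum((m_ps[(j, k_)] - m_p[j] - m_s[k_] + gm) ** 2
                        for j in postures for k_ in stimuli)
    ss_gps = sum(
        n_per[g] * (m_gps[(g, j, k_)] - m_gp[(g, j)] - m_gs[(g, k_)]
                    - m_ps[(j, k_)] + m_g[g] + m_p[j] + m_s[k_] - gm) ** 2
        for g in groups for j in postures for k_ in stimuli
    )
    ss_total = sum((v - gm) ** 2 for v in y.values())
    ss_pserr = ss_total - (ss_g + ss_subj + ss_p + ss_gp + ss_perr
                           + ss_s + ss_gs + ss_serr + ss_ps + ss_gps)

    df_subj = n_sub - a
    out = {
        "group": (ss_g / (a - 1)) / (ss_subj / df_subj),
        "posture": (ss_p / (p - 1)) / (ss_perr / (df_subj * (p - 1))),
        "group:posture": (ss_gp / ((a - 1) * (p - 1)))
        / (ss_perr / (df_subj * (p - 1))),
        "stimulus": (ss_s / (s - 1)) / (ss_serr / (df_subj * (s - 1))),
        "group:stimulus": (ss_gs / ((a - 1) * (s - 1)))
        / (ss_serr / (df_subj * (s - 1))),
        "posture:stimulus": (ss_ps / ((p - 1) * (s - 1)))
        / (ss_pserr / (df_subj * (p - 1) * (s - 1))),
        "group:posture:stimulus": (ss_gps / ((a - 1) * (p - 1) * (s - 1)))
        / (ss_pserr / (df_subj * (p - 1) * (s - 1))),
    }
    return out


def bh_stepup_brute(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
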