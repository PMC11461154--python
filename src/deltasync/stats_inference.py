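"""Split-plot repeated-measures ANOVA and multiplicity control.

The inference stage tests, separately for each electrode pair, a mixed
design with one between-participant factor (Group: expert vs novice) and
two crossed within-participant factors (Posture: sitting/standing,
Stimulus: symbolic/geometric), one value per participant per cell.

The decomposition follows the classical univariate approach to repeated
measures via orthonormal within-subject contrasts: for each within effect
the participant x cell matrix is projected onto a Helmert contrast basis,
and the effect, its Group interaction, and the matching participant-nested
error stratum are sums of squares in that contrast space. The between-
participant stratum (Group) is a one-way ANOVA on participant means. Each
within effect carries a Greenhouse-Geisser epsilon estimated from the
pooled covariance of its contrast scores (identically 1 for 2-level
factors, where sphericity holds by construction); GG-adjusted p-values
scale both degrees of freedom by epsilon.

Multiplicity: pairwise level contrasts are Bonferroni-protected, and the
per-pair GG p-values of one effect are Benjamini-Hochberg adjusted across
the 66-pair family. The arithmetic is vectorised over electrode pairs, so
a 66-pair family costs one pass, not 66.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .core_data import DesignError

__all__ = [
    "AnovaResult",
    "Comparison",
    "mixed_rm_anova",
    "gg_epsilon",
    "bonferroni_comparisons",
    "bh_fdr",
    "anova_by_pair",
    "significance_report",
    "format_report",
    "add_design_columns",
]

MAIN_EFFECTS = ("group", "posture", "stimulus", "group:posture", "group:stimulus")


@dataclass
class Comparison:
    contrast: str          # "A vs B"
    direction: str         # "A > B" by observed means
    p: float               # raw p of the level contrast
    p_bonferroni: float    # p * number of contrasts, capped at 1
    mean_diff: float


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple              # (numerator, denominator), unadjusted
    p_unc: float
    epsilon: float
    p_gg: float
    comparisons: list = field(default_factory=list)
    p_fdr: float | None = None


def gg_epsilon(within_covariance: np.ndarray, contrast: np.ndarray | None = None,
               already_contrasted: bool = False) -> float:
    """Greenhouse-Geisser epsilon from a within-cell covariance matrix.

    ``within_covariance`` is the k x k covariance of the within-condition
    values (or, with ``already_contrasted=True``, the q x q covariance of
    orthonormal contrast scores). Returns epsilon clipped to ``[1/q, 1]``
    where ``q`` is the contrast dimension.
    """
    s = np.asarray(within_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if already_contrasted:
        st = s
    else:
        k = s.shape[0]
        if contrast is None:
            contrast = linalg.helmert(k).T  # k x (k-1), orthonormal
        st = contrast.T @ s @ contrast
    q = st.shape[0]
    tr = np.trace(st)
    tr2 = np.trace(st @ st)
    if tr2 <= 1e-30:
        return 1.0
    eps = tr**2 / (q * tr2)
    return float(np.clip(eps, 1.0 / q, 1.0))


# ---------------------------------------------------------------------------
# Numeric core (batched over an arbitrary leading axis, e.g. electrode pairs)
# ---------------------------------------------------------------------------

def _f_and_p(ss_eff, df1, ss_err, df2, eps=1.0):
    ss_eff = np.asarray(ss_eff, float)
    ss_err = np.asarray(ss_err, float)
    tiny_err = ss_err <= 1e-30 * np.maximum(1.0, np.abs(ss_eff))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_eff / df1) / (ss_err / df2)
    f = np.where(tiny_err, np.where(ss_eff <= 1e-30, 0.0, np.inf), f)
    p_unc = stats.f.sf(f, df1, df2)
    p_gg = stats.f.sf(f, np.asarray(eps) * df1, np.asarray(eps) * df2)
    return f, p_unc, p_gg


def _within_effect_contrasts(levels, within):
    """Orthonormal contrast matrix per within effect (Helmert Kroneckers)."""
    helmerts = [linalg.helmert(len(lv)).T for lv in levels]
    units = [np.full((len(lv), 1), 1 / np.sqrt(len(lv))) for lv in levels]
    effects = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            c = np.ones((1, 1))
            for i in range(len(within)):
                c = np.kron(c, helmerts[i] if i in combo else units[i])
            effects.append((":".join(within[i] for i in combo), c))
    return effects


def _anova_batch(y: np.ndarray, gidx, effect_contrasts, between: str) -> dict:
    """Split-plot ANOVA on ``y`` of shape (..., n_subjects, n_cells).

    ``gidx``: list of subject index arrays per group. Returns a dict
    effect -> (F, df1, df2, epsilon, p_unc, p_gg), each entry an array over
    the leading batch axes.
    """
    n, w = y.shape[-2], y.shape[-1]
    a = len(gidx)
    out = {}

    # Between stratum: one-way ANOVA on orthonormally scaled subject means.
    z0 = y.mean(axis=-1) * np.sqrt(w)
    gmean = z0.mean(axis=-1)
    ss_g = np.zeros(z0.shape[:-1])
    ss_sg = np.zeros(z0.shape[:-1])
    for ix in gidx:
        mg = z0[..., ix].mean(axis=-1)
        ss_g += len(ix) * (mg - gmean) ** 2
        ss_sg += ((z0[..., ix] - mg[..., None]) ** 2).sum(axis=-1)
    f, p_unc, p_gg = _f_and_p(ss_g, a - 1, ss_sg, n - a)
    out[between] = (f, a - 1, n - a, np.ones_like(np.asarray(f, float)),
                    p_unc, p_gg)

    for name, c in effect_contrasts:
        q = c.shape[1]
        z = y @ c  # (..., n, q)
        zbar = z.mean(axis=-2)
        ss_eff = n * (zbar**2).sum(axis=-1)
        ss_int = np.zeros(ss_eff.shape)
        ss_err = np.zeros(ss_eff.shape)
        pooled = np.zeros(ss_eff.shape + (q, q))
        for ix in gidx:
            zg = z[..., ix, :]
            mg = zg.mean(axis=-2)
            d = mg - zbar
            ss_int += len(ix) * (d**2).sum(axis=-1)
            r = zg - mg[..., None, :]
            ss_err += (r**2).sum(axis=(-1, -2))
            pooled += np.einsum("...nq,...nr->...qr", r, r)
        pooled /= n - a
        tr = np.trace(pooled, axis1=-2, axis2=-1)
        tr2 = np.einsum("...qr,...rq->...", pooled, pooled)
        with np.errstate(divide="ignore", invalid="ignore"):
            eps = np.where(tr2 <= 1e-30, 1.0, tr**2 / (q * np.where(
                tr2 <= 1e-30, 1.0, tr2)))
        eps = np.clip(eps, 1.0 / q, 1.0)
        f, p_unc, p_gg = _f_and_p(ss_eff, q, ss_err, (n - a) * q, eps)
        out[name] = (f, q, (n - a) * q, eps, p_unc, p_gg)
        f, p_unc, p_gg = _f_and_p(ss_int, (a - 1) * q, ss_err, (n - a) * q, eps)
        out[f"{between}:{name}"] = (f, (a - 1) * q, (n - a) * q, eps, p_unc,
                                    p_gg)
    return out


def _group_indices(groups: np.ndarray):
    glevels = sorted(pd.unique(groups))
    if len(glevels) < 2:
        raise DesignError("need at least 2 groups")
    gidx = [np.flatnonzero(groups == g) for g in glevels]
    if any(len(ix) < 2 for ix in gidx):
        raise DesignError("need at least 2 participants per group")
    return glevels, gidx


def _pivot_design(table: pd.DataFrame, value, subject, between, within):
    """Participant x cell matrix plus group labels; errors name missing cells."""
    within = list(within)
    levels = [np.array(sorted(table[f].unique())) for f in within]
    for f, lv in zip(within, levels):
        if len(lv) < 2:
            raise DesignError(f"within factor {f!r} has fewer than 2 levels")
    cells = list(itertools.product(*levels))
    counts = table.pivot_table(index=subject, columns=within, values=value,
                               aggfunc="count")
    full = table.pivot_table(index=subject, columns=within, values=value,
                             aggfunc="mean")
    for cell in cells:
        key = cell if len(cell) > 1 else cell[0]
        if key not in counts.columns:
            raise DesignError(f"design cell {dict(zip(within, cell))} has no data")
        col = counts[key]
        if col.isna().any() or (col != 1).any():
            subj = list(col[(col != 1) | col.isna()].index)
            raise DesignError(
                f"cell {dict(zip(within, cell))} not balanced for "
                f"participant(s) {subj} (need exactly one value)"
            )
    order = [cell if len(cell) > 1 else cell[0] for cell in cells]
    y = full[order].to_numpy(dtype=float)
    groups = table.groupby(subject)[between].agg(
        lambda g: g.iloc[0] if g.nunique() == 1 else np.nan
    )
    if groups.isna().any():
        raise DesignError("between factor varies within a participant")
    return y, groups.loc[full.index].to_numpy(), levels, within


def mixed_rm_anova(table: pd.DataFrame, *, value: str = "value",
                   subject: str = "participant", between: str = "group",
                   within=("posture", "stimulus")) -> dict:
    """Mixed (split-plot) repeated-measures ANOVA.

    Returns a dict of effect name -> :class:`AnovaResult` for the between
    main effect, every within effect and its interaction with the between
    factor. Effect keys are lowercase factor names joined with ``:``
    (e.g. ``"group:posture"``).
    """
    y, groups, levels, within = _pivot_design(table, value, subject, between,
                                              within)
    _, gidx = _group_indices(groups)
    contrasts = _within_effect_contrasts(levels, within)
    raw = _anova_batch(y, gidx, contrasts, between)
    return {
        name: AnovaResult(name, float(f), (df1, df2), float(p_unc),
                          float(eps), float(p_gg))
        for name, (f, df1, df2, eps, p_unc, p_gg) in raw.items()
    }


def bonferroni_comparisons(table: pd.DataFrame, factor: str, *,
                           value: str = "value", subject: str = "participant",
                           alpha: float = 0.05,
                           subset: pd.Series | None = None) -> list:
    """Bonferroni-protected pairwise level contrasts of one factor.

    Between-participant factors (constant within participant) use pooled
    two-sample t-tests on participant means; within factors use paired
    t-tests. ``p_bonferroni = p * n_contrasts`` capped at 1. ``subset``
    optionally restricts the rows (e.g. the standing posture only, for
    simple effects inside an interaction).
    """
    df = table if subset is None else table[subset]
    per = df.groupby([subject, factor], observed=True)[value].mean().unstack(factor)
    levels = sorted(per.columns)
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} needs >= 2 levels")
    is_between = (
        table.groupby(subject, observed=True)[factor].nunique().max() == 1
    )
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out = []
    for la, lb in pairs:
        if is_between:
            xa = per[la].dropna().to_numpy()
            xb = per[lb].dropna().to_numpy()
            t, p = stats.ttest_ind(xa, xb, equal_var=True)
            diff = xa.mean() - xb.mean()
        else:
            both = per[[la, lb]].dropna()
            t, p = stats.ttest_rel(both[la], both[lb])
            diff = float(both[la].mean() - both[lb].mean())
        hi, lo = (la, lb) if diff >= 0 else (lb, la)
        out.append(
            Comparison(
                contrast=f"{la} vs {lb}",
                direction=f"{hi} > {lo}",
                p=float(p),
                p_bonferroni=float(min(1.0, p * m)),
                mean_diff=float(diff),
            )
        )
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Per-pair orchestration and reporting
# ---------------------------------------------------------------------------

def add_design_columns(psv_table: pd.DataFrame) -> pd.DataFrame:
    """Split 'Symbolic-Sitting'-style condition labels into factor columns."""
    out = psv_table.copy()
    parts = out["condition"].str.split("-", n=1, expand=True)
    out["stimulus"] = parts[0]
    out["posture"] = parts[1]
    return out


def anova_by_pair(design: pd.DataFrame, *, value: str = "psv",
                  subject: str = "participant", between: str = "group",
                  within=("posture", "stimulus")) -> pd.DataFrame:
    """Mixed RM-ANOVA per electrode pair, with BH-FDR across pairs.

    ``design`` must carry columns participant, group, pair_a, pair_b, the
    within-factor columns and the value column. Returns one row per
    (pair, effect) with F, df, epsilon, p_gg and p_fdr (BH across the pair
    family, separately per effect). All pairs are computed in one batched
    pass.
    """
    within = list(within)
    levels = [np.array(sorted(design[f].unique())) for f in within]
    for f, lv in zip(within, levels):
        if len(lv) < 2:
            raise DesignError(f"within factor {f!r} has fewer than 2 levels")
    cells = list(itertools.product(*levels))
    pair_cols = ["pair_a", "pair_b"]
    pairs = sorted(set(zip(design["pair_a"], design["pair_b"])))

    counts = design.pivot_table(index=subject, columns=pair_cols + within,
                                values=value, aggfunc="count")
    full = design.pivot_table(index=subject, columns=pair_cols + within,
                              values=value, aggfunc="mean")
    order = pd.MultiIndex.from_tuples(
        [p + c for p in pairs for c in cells],
        names=pair_cols + within,
    )
    missing = [c for c in order if c not in counts.columns]
    if missing or counts[order].isna().any().any() or (counts[order] != 1).any().any():
        raise DesignError(
            "unbalanced design: every participant needs exactly one value "
            "per (pair, cell); first problem at "
            f"{missing[0] if missing else 'a duplicated/missing cell'}"
        )
    n_sub, w = len(full.index), len(cells)
    y = full[order].to_numpy(dtype=float).reshape(n_sub, len(pairs), w)
    y = np.moveaxis(y, 0, 1)  # (pairs, subjects, cells)

    groups = design.groupby(subject)[between].first().loc[full.index].to_numpy()
    _, gidx = _group_indices(groups)
    contrasts = _within_effect_contrasts(levels, within)
    raw = _anova_batch(y, gidx, contrasts, between)

    frames = []
    for name, (f, df1, df2, eps, p_unc, p_gg) in raw.items():
        frames.append(pd.DataFrame({
            "pair_a": [p[0] for p in pairs],
            "pair_b": [p[1] for p in pairs],
            "effect": name,
            "F": np.atleast_1d(f),
            "df1": df1,
            "df2": df2,
            "epsilon": np.atleast_1d(eps),
            "p_gg": np.atleast_1d(p_gg),
            "p_fdr": bh_fdr(np.atleast_1d(p_gg)),
        }))
    return pd.concat(frames, ignore_index=True)


def _group_stats(design, value, subset=None):
    df = design if subset is None else design[subset]
    per = df.groupby(["participant", "group"], observed=True)[value].mean()
    per = per.reset_index()
    stats_ = {}
    for g, sub in per.groupby("group"):
        stats_[g] = (float(sub[value].mean()), float(sub[value].std(ddof=1)))
    return stats_


def significance_report(anova_df: pd.DataFrame, design: pd.DataFrame, *,
                        value: str = "psv", alpha: float = 0.05,
                        baseline_df: pd.DataFrame | None = None,
                        effects=("group", "group:posture")) -> pd.DataFrame:
    """Table of effects passing GG, Bonferroni and FDR criteria.

    One row per surviving (pair, effect), with group means (SD) -- for
    Group x Posture interactions, means within the posture whose simple
    effect is significant -- and, when ``baseline_df`` (per-pair rest
    ANOVA) is given, the matching baseline Group p-value and a flag for
    pairs already differing at baseline.
    """
    rows = []
    for _, r in anova_df.iterrows():
        if r["effect"] not in effects:
            continue
        if not (r["p_gg"] < alpha and r["p_fdr"] < alpha):
            continue
        pa, pb = r["pair_a"], r["pair_b"]
        mask = (design["pair_a"] == pa) & (design["pair_b"] == pb)
        sub = design[mask]
        if r["effect"] == "group":
            comp = bonferroni_comparisons(sub, "group", value=value)[0]
            if comp.p_bonferroni >= alpha:
                continue
            gstats = _group_stats(sub, value)
            direction = comp.direction
            comp_p = comp.p_bonferroni
        else:  # group x posture: simple group effects per posture, Bonf x2
            postures = sorted(sub["posture"].unique())
            simple = [
                (post, bonferroni_comparisons(
                    sub, "group", value=value, subset=sub["posture"] == post
                )[0])
                for post in postures
            ]
            m = len(simple)
            sig = [(post, c) for post, c in simple
                   if min(1.0, c.p * m) < alpha]
            if not sig:
                continue
            post, comp = min(sig, key=lambda pc: pc[1].p)
            gstats = _group_stats(sub, value, subset=sub["posture"] == post)
            direction = f"{post}: {comp.direction}"
            comp_p = min(1.0, comp.p * m)
        base_p = np.nan
        if baseline_df is not None:
            bmask = (
                (baseline_df["pair_a"] == pa)
                & (baseline_df["pair_b"] == pb)
                & (baseline_df["effect"] == "group")
            )
            if bmask.any():
                base_p = float(baseline_df.loc[bmask, "p_gg"].iloc[0])
        rows.append(
            {
                "pair": f"{pa}-{pb}",
                "effect": r["effect"],
                "F": r["F"],
                "df1": r["df1"],
                "df2": r["df2"],
                "p_gg": r["p_gg"],
                "p_fdr": r["p_fdr"],
                "comparison": direction,
                "p_comparison": comp_p,
                "mean_expert": gstats.get("expert", (np.nan, np.nan))[0],
                "sd_expert": gstats.get("expert", (np.nan, np.nan))[1],
                "mean_novice": gstats.get("novice", (np.nan, np.nan))[0],
                "sd_novice": gstats.get("novice", (np.nan, np.nan))[1],
                "baseline_p_gg": base_p,
                "baseline_significant": bool(base_p < alpha)
                if np.isfinite(base_p) else False,
            }
        )
    cols = ["pair", "effect", "F", "df1", "df2", "p_gg", "p_fdr",
            "comparison", "p_comparison", "mean_expert", "sd_expert",
            "mean_novice", "sd_novice", "baseline_p_gg",
            "baseline_significant"]
    return pd.DataFrame(rows, columns=cols)


def format_report(report: pd.DataFrame, title: str = "") -> str:
    """Human-readable text table (pair, F(df), pGG, pFDR, means)."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    if report.empty:
        lines.append("(no significant effects)")
        return "\n".join(lines) + "\n"
    for _, r in report.iterrows():
        lines.append(
            f"{r['pair']:<12} {r['effect']:<16} "
            f"F({r['df1']:.0f},{r['df2']:.0f})={r['F']:.2f}  "
            f"pGG={r['p_gg']:.4f}  pFDR={r['p_fdr']:.4f}  "
            f"{r['comparison']}  "
            f"experts {r['mean_expert']:.2f} ({r['sd_expert']:.2f})  "
            f"novices {r['mean_novice']:.2f} ({r['sd_novice']:.2f})"
            + (f"  baseline pGG={r['baseline_p_gg']:.2f}"
               if np.isfinite(r["baseline_p_gg"]) else "")
        )
    return "\n".join(lines) + "\n"
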