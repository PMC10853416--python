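"""Two statistical engines for the channel x frequency analyses.

* :func:`permutation_anova` / :func:`anova_grid` — one-way permutation
  ANOVA of absolute PSD across the channel x frequency-bin grid for the
  three text-type conditions, Bonferroni-corrected over all tested cells.
  Permutation inference is used because no distributional form is assumed
  for the per-cell observations.

* :func:`run_cascade` — for each (site, band measure, grouping variable)
  cell, a two-group test chosen by assumption checks: Levene's test for
  homogeneity of variances and a Shapiro-Wilk test per group for
  normality.  Both hold -> Student's t; normal but heteroscedastic ->
  Welch's t; any non-normal group -> Mann-Whitney U.  Raw p-values are
  pooled over the whole cascade and thresholded by the Benjamini-Hochberg
  FDR procedure; Cohen's d (pooled-SD standardized mean difference)
  accompanies every cell.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as ss

from .io import GROUP_VARIABLES, ContractError
from .spectral import BAND_NAMES

__all__ = [
    "MEASURES",
    "permutation_anova",
    "anova_grid",
    "choose_test",
    "run_cascade",
    "bh_fdr",
    "cohens_d",
    "participant_condition_psd",
]

logger = logging.getLogger(__name__)

#: the six per-site measures entering the cascade
MEASURES = (*BAND_NAMES, "brain_rate")


def _f_from_blocks(values: np.ndarray, sizes: list[int]) -> np.ndarray:
    """One-way ANOVA F for observations arranged in label blocks.

    ``values`` has shape (..., n) with group g occupying a contiguous
    column block of ``sizes[g]``; F is computed along the last axis.
    """
    n = values.shape[-1]
    k = len(sizes)
    total = values.sum(axis=-1)
    sst = (values**2).sum(axis=-1) - total**2 / n
    ssb = -(total**2) / n
    pos = 0
    for sz in sizes:
        gsum = values[..., pos : pos + sz].sum(axis=-1)
        ssb = ssb + gsum**2 / sz
        pos += sz
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return f


def permutation_anova(
    groups: list[np.ndarray], n_perm: int = 1999, seed: int = 0
) -> tuple[float, float]:
    """One-way permutation ANOVA over k groups.

    Returns ``(F_obs, p_perm)`` with the add-one estimator
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``; condition labels are
    permuted uniformly.  An infinite observed F (zero within-group
    variance, distinct means) beats every finite permuted F; an all-equal
    input yields F = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ContractError("need >= 2 groups with >= 2 observations each")
    sizes = [len(g) for g in groups]
    values = np.concatenate(groups)
    n = len(values)
    f_obs = float(_f_from_blocks(values, sizes))
    if np.isnan(f_obs):  # zero variance everywhere
        return 0.0, 1.0

    rng = np.random.default_rng(seed)
    idx = rng.permuted(
        np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
    )
    f_perm = _f_from_blocks(values[idx], sizes)
    f_perm = np.nan_to_num(f_perm, nan=0.0, posinf=np.inf)
    if np.isinf(f_obs):
        exceed = np.isinf(f_perm).sum()
    else:
        exceed = int((f_perm >= f_obs - 1e-12).sum())
    return f_obs, (1 + exceed) / (1 + n_perm)


def participant_condition_psd(features) -> pd.DataFrame:
    """Per-(participant, condition, channel, frequency-bin) mean PSD —
    the observation unit of the text-type grid ANOVA."""
    rows = []
    for f in features:
        for freq, p in zip(f.freqs_hz, f.psd_abs):
            rows.append((f.participant_id, f.text_type, f.channel, freq, p))
    df = pd.DataFrame(
        rows, columns=["participant_id", "condition", "channel", "freq_hz", "psd"]
    )
    return (
        df.groupby(["participant_id", "condition", "channel", "freq_hz"])["psd"]
        .mean()
        .reset_index()
    )


def anova_grid(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation ANOVA per (channel, frequency bin) with Bonferroni.

    ``table`` holds one row per (participant, condition, channel,
    freq_hz) with a ``psd`` value; every cell must have all k conditions.
    The Bonferroni family is *all* tested cells; one shared set of
    permutations is used across cells.  Cells missing a condition are
    skipped with a log entry.
    """
    conditions = sorted(table["condition"].unique())
    k = len(conditions)
    if k < 2:
        raise ContractError("grid ANOVA needs >= 2 conditions")

    wide = table.pivot_table(
        index=["channel", "freq_hz"],
        columns=["condition", "participant_id"],
        values="psd",
    )
    complete = wide.dropna(axis=0)
    skipped = wide.index.difference(complete.index)
    for ch, fr in skipped:
        logger.warning("anova_grid: skipping (%s, %g Hz): missing cell", ch, fr)

    cols = complete.columns
    sizes = [int((cols.get_level_values(0) == c).sum()) for c in conditions]
    order = np.argsort(cols.get_level_values(0), kind="stable")
    values = complete.to_numpy()[:, order]  # (n_cells, n_obs), label blocks
    n_cells, n_obs = values.shape

    f_obs = _f_from_blocks(values, sizes)
    f_obs = np.nan_to_num(f_obs, nan=0.0, posinf=np.inf)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_cells, dtype=np.int64)
    chunk = max(1, int(2e7 // max(1, n_cells * n_obs)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = rng.permuted(
            np.broadcast_to(np.arange(n_obs), (m, n_obs)).copy(), axis=1
        )
        f_perm = _f_from_blocks(values[:, idx], sizes)  # (n_cells, m)
        f_perm = np.nan_to_num(f_perm, nan=0.0, posinf=np.inf)
        exceed += (f_perm >= f_obs[:, None] - 1e-12).sum(axis=1)
        done += m
    p_perm = (1 + exceed) / (1 + n_perm)
    p_perm[f_obs == 0.0] = 1.0

    m_tests = n_cells
    out = pd.DataFrame(
        {
            "channel": complete.index.get_level_values(0),
            "freq_bin_hz": complete.index.get_level_values(1),
            "F_obs": f_obs,
            "p_perm": p_perm,
            "significant": p_perm <= alpha / m_tests,
        }
    ).reset_index(drop=True)
    out.attrs["n_comparisons"] = m_tests
    out.attrs["alpha"] = alpha
    return out


def choose_test(
    group_a: np.ndarray, group_b: np.ndarray, alpha_assumption: float = 0.05
) -> str:
    """Pick the two-group test from Levene + Shapiro-Wilk outcomes.

    Both groups normal and homoscedastic -> ``student_t``; both normal but
    heteroscedastic -> ``welch_t``; any non-normal group (including a
    constant group, where Shapiro-Wilk is undefined) -> ``mann_whitney_u``.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ContractError("assumption checks need >= 3 values per group")

    normal = _shapiro_normal(a, alpha_assumption) and _shapiro_normal(
        b, alpha_assumption
    )
    if not normal:
        return "mann_whitney_u"
    return (
        "student_t"
        if _levene_mean_p(a, b) > alpha_assumption
        else "welch_t"
    )


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = ss.shapiro(x).pvalue
    return bool(p > alpha) and not np.isnan(p)


def _levene_mean_p(a: np.ndarray, b: np.ndarray) -> float:
    """Levene's test with mean centering: one-way ANOVA F on the absolute
    deviations from each group's mean (k = 2)."""
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    na, nb = len(za), len(zb)
    n = na + nb
    grand = (za.sum() + zb.sum()) / n
    ssb = na * (za.mean() - grand) ** 2 + nb * (zb.mean() - grand) ** 2
    ssw = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    if ssw == 0:
        return 0.0 if ssb > 0 else 1.0
    f = ssb / (ssw / (n - 2))
    return float(ss.f.sf(f, 1, n - 2))


def _t_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    """Two-sided independent-samples t-test p-value (Student or Welch)."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        dof = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        dof = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    if se == 0:
        return 1.0
    t = (a.mean() - b.mean()) / se
    return float(2.0 * ss.t.sf(abs(t), dof))


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (signed; tables print |d|)."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ContractError("Cohen's d needs >= 2 values per group")
    s_pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / s_pooled)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at rate ``q``.

    Returns a boolean pass flag per input p-value and the realized
    adjusted alpha — the largest ``p_(i)`` with ``p_(i) <= (i/m) q`` (0 when
    nothing passes).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * q
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    cutoff = ranked[np.nonzero(below)[0].max()]
    return p <= cutoff, float(cutoff)


def _two_group_test(a: np.ndarray, b: np.ndarray, alpha_assumption: float):
    test = choose_test(a, b, alpha_assumption)
    if test == "student_t":
        p = _t_p(a, b, equal_var=True)
    elif test == "welch_t":
        p = _t_p(a, b, equal_var=False)
    else:
        p = float(ss.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return test, p


def run_cascade(
    features_df: pd.DataFrame,
    metadata: list,
    variables: tuple[str, ...] | None = None,
    sites: list[str] | None = None,
    measures: tuple[str, ...] = MEASURES,
    q: float = 0.05,
    alpha_assumption: float = 0.05,
    unit: str = "stimulus",
    pooling: str = "all",
) -> pd.DataFrame:
    """The full (site x measure x variable) two-group test cascade.

    ``features_df`` is the stimulus-level relative-measure frame from
    :func:`eegfiction.spectral.features_frame` (columns: participant_id,
    channel, the five band names, brain_rate).  ``unit="participant"``
    averages within participant first (the non-pseudoreplicated
    alternative).  BH-FDR is applied to the p-values pooled over the whole
    cascade (``pooling="all"``) or per variable.
    """
    if unit not in ("stimulus", "participant"):
        raise ContractError(f"unknown observation unit {unit!r}")
    if pooling not in ("all", "per_variable"):
        raise ContractError(f"unknown pooling mode {pooling!r}")
    variables = tuple(GROUP_VARIABLES) if variables is None else variables
    sites = sorted(features_df["channel"].unique()) if sites is None else sites
    meta_by_id = {m.participant_id: m for m in metadata}

    if unit == "participant":
        features_df = (
            features_df.groupby(["participant_id", "channel"], as_index=False)[
                list(measures)
            ].mean()
        )

    # numpy views per site, so the 930-cell loop avoids frame indexing
    pid_values = features_df["participant_id"].to_numpy()
    by_site = {}
    for site, idx in features_df.groupby("channel").groups.items():
        loc = features_df.index.get_indexer(idx)
        by_site[site] = (
            pid_values[loc],
            {m: features_df[m].to_numpy()[loc] for m in measures},
        )

    records = []
    for variable in variables:
        levels = [l for l in GROUP_VARIABLES[variable] if l != "rest"]
        members = {
            lvl: {
                pid for pid, m in meta_by_id.items() if m.level(variable) == lvl
            }
            for lvl in levels
        }
        if any(len(v) == 0 for v in members.values()):
            logger.warning(
                "cascade: variable %r has an empty group; skipped", variable
            )
            continue
        for site in sites:
            pids, cols = by_site[site]
            in_a = np.isin(pids, list(members[levels[0]]))
            in_b = np.isin(pids, list(members[levels[1]]))
            for measure in measures:
                a = cols[measure][in_a]
                b = cols[measure][in_b]
                test, p = _two_group_test(a, b, alpha_assumption)
                records.append(
                    {
                        "site": site,
                        "measure": measure,
                        "variable": variable,
                        "group_a": levels[0],
                        "group_b": levels[1],
                        "test_used": test,
                        "p_raw": p,
                        "cohens_d": cohens_d(a, b),
                        "mean_a": float(a.mean()),
                        "mean_b": float(b.mean()),
                        "sd_a": float(a.std(ddof=1)),
                        "sd_b": float(b.std(ddof=1)),
                        "n_a": len(a),
                        "n_b": len(b),
                    }
                )
    out = pd.DataFrame.from_records(records)
    if out.empty:
        out.attrs["adjusted_alpha"] = 0.0
        return out
    if pooling == "all":
        passes, adj = bh_fdr(out["p_raw"].to_numpy(), q)
        out["p_passes_fdr"] = passes
        out.attrs["adjusted_alpha"] = adj
    else:
        out["p_passes_fdr"] = False
        adj_by_var = {}
        for variable, idx in out.groupby("variable").groups.items():
            passes, adj = bh_fdr(out.loc[idx, "p_raw"].to_numpy(), q)
            out.loc[idx, "p_passes_fdr"] = passes
            adj_by_var[variable] = adj
        out.attrs["adjusted_alpha"] = adj_by_var
    return out
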