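"""Nonparametric cohort statistics and the study-table builders.

The statistical layer of the analysis: Mann-Whitney rank-sum tests between
the sedentary and exercising groups, Wilcoxon signed-rank tests for paired
within-subject contrasts (WB vs NWB segments, superficial vs deep layers)
and Spearman rank correlations for the thickness-confounding analysis.

At the study's sample sizes (8 and 9 subjects) exact small-sample p-values
are the defensible default, so ``mode="auto"`` selects the exact null
distribution whenever it is available without tie corrections (total
n <= 20 untied for Mann-Whitney, n <= 15 non-tied differences for
Wilcoxon, n <= 8 for Spearman via full permutation) and falls back to the
tie-corrected normal / t approximations otherwise.  All tests are
two-sided; 0.05 is the conventional significance level and no
multiple-testing correction is applied (a deliberate mirror of common
practice in small imaging cohorts -- see the methods note for the caveat).

Computation of the classical tests is delegated to scipy.stats; this module
fixes the mode-selection policy, the tidy result containers and the table
builders.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman",
    "build_tables",
    "confound_analysis",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparison:
    """A two-group cell of a cohort table: descriptives plus the test."""

    label: str
    group_a: str
    group_a_mean: float
    group_a_sd: float
    group_b: str
    group_b_mean: float
    group_b_sd: float
    statistic: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its sample size and p-value."""

    n: int
    rho: float
    p_value: float

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| > 1")


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U of x, p).

    mode 'exact' enumerates the null distribution of U (valid without
    ties), 'approx' uses the tie-corrected normal approximation with
    continuity correction, 'auto' picks exact when n_x + n_y <= 20 and the
    pooled sample is tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if mode not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    if mode == "auto":
        mode = "exact" if (pooled.size <= 20 and not _has_ties(pooled)) else "approx"
    if mode == "exact" and _has_ties(pooled):
        logger.info("ties present; falling back to the normal approximation")
        mode = "approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(paired_diffs, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (their count is logged); returns (W, p)
    where W is the smaller signed-rank sum.  All-zero differences give the
    degenerate p = 1 with a warning.  mode 'exact' enumerates the 2^n sign
    patterns (n <= 15 by 'auto'), 'approx' is the tie-corrected normal
    approximation.
    """
    d = np.asarray(paired_diffs, dtype=float)
    n_zero = int(np.sum(d == 0))
    if n_zero:
        logger.info("dropping %d zero difference(s) before the signed-rank test",
                    n_zero)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; degenerate test (p = 1)",
                      stacklevel=2)
        return 0.0, 1.0
    if d.size < 2:
        raise ValueError("need at least 2 non-zero paired differences")
    if mode not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    tied_abs = _has_ties(np.abs(d))
    if mode == "auto":
        mode = "exact" if (d.size <= 15 and not tied_abs) else "approx"
    if mode == "exact" and tied_abs:
        logger.info("tied |differences|; falling back to the approximation")
        mode = "approx"
    method = "exact" if mode == "exact" else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact permutation p-value for |rho| by enumerating all n! orderings."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_all = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_all - ry_all.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum()) * np.sqrt((ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y, mode: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with mid-ranked ties.

    p from the exact permutation distribution for n <= 8 (mode 'auto'),
    otherwise the t approximation.  A constant input vector leaves rho
    undefined (NaN) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input; Spearman rho undefined", stacklevel=2)
        return CorrelationResult(n=int(x.size), rho=float("nan"),
                                 p_value=float("nan"))
    rho, p = sps.spearmanr(x, y)
    rho = float(np.clip(rho, -1.0, 1.0))
    if mode == "exact" or (mode == "auto" and x.size <= 8):
        p = _spearman_exact_p(x, y, rho)
    return CorrelationResult(n=int(x.size), rho=rho, p_value=float(p))


# --------------------------------------------------------------------------
# table builders
# --------------------------------------------------------------------------

def _group_cells(df: pd.DataFrame, value: str, groups: tuple[str, str]):
    a = df.loc[df["group"] == groups[0], value].dropna().to_numpy()
    b = df.loc[df["group"] == groups[1], value].dropna().to_numpy()
    return a, b


def _describe_and_test(df, value, groups, label) -> GroupComparison | None:
    a, b = _group_cells(df, value, groups)
    if a.size < 2 or b.size < 2:
        logger.warning("skipping %s: fewer than 2 complete subjects per group",
                       label)
        return None
    u, p = mann_whitney(a, b)
    return GroupComparison(
        label=label,
        group_a=groups[0], group_a_mean=float(a.mean()),
        group_a_sd=float(a.std(ddof=1)),
        group_b=groups[1], group_b_mean=float(b.mean()),
        group_b_sd=float(b.std(ddof=1)),
        statistic=u, p_value=p, test_name="mann-whitney",
    )


def _paired_p(df: pd.DataFrame, value: str, within: str,
              levels: tuple[str, str]) -> float:
    """Wilcoxon p for a within-subject contrast, pairwise-complete."""
    wide = df.pivot_table(index="subject_id", columns=within, values=value,
                          aggfunc="mean")
    if not set(levels) <= set(wide.columns):
        return float("nan")
    wide = wide.dropna(subset=list(levels))
    if len(wide) < 2:
        return float("nan")
    diffs = (wide[levels[0]] - wide[levels[1]]).to_numpy()
    _, p = wilcoxon_signed_rank(diffs)
    return p


def build_tables(
    summaries: pd.DataFrame,
    groups: tuple[str, str] = ("exercise", "sedentary"),
    pool_compartments: bool = False,
) -> dict[str, pd.DataFrame]:
    """Build the three cohort tables from a tidy summary frame.

    table1: cartilage thickness by compartment x segment with the
    between-group rank-sum p-value.  table2: pre-contrast T1 by segment x
    layer with the between-group p per row and the paired
    superficial-vs-deep p per group.  table3: superficial-layer [Gd] by
    segment with the between-group p and the paired WB-vs-NWB p per group.

    Layer T1 and [Gd] rows are per compartment by default;
    ``pool_compartments=True`` averages the two compartments per subject
    first.
    """
    req = {"subject_id", "group", "compartment", "segment", "layer"}
    if not req <= set(summaries.columns):
        raise ValueError(f"summary frame lacks columns {req - set(summaries.columns)}")
    df = summaries.copy()
    missing = df["t1pre_ms"].isna() & (df["n_pixels"] == 0)
    if missing.any():
        logger.warning("%d empty-ROI rows handled pairwise-complete",
                       int(missing.sum()))

    # ---- table 1: thickness -------------------------------------------
    rows1 = []
    full = df[df["layer"] == "full"]
    for segment in ("WB", "NWB"):
        for compartment in sorted(full["compartment"].unique()):
            sub = full[(full["segment"] == segment)
                       & (full["compartment"] == compartment)]
            cmp_ = _describe_and_test(sub, "thickness_mm", groups,
                                      f"{segment} {compartment}")
            if cmp_ is None:
                continue
            rows1.append({
                "segment": segment, "compartment": compartment,
                f"{groups[0]}_mean": cmp_.group_a_mean,
                f"{groups[0]}_sd": cmp_.group_a_sd,
                f"{groups[1]}_mean": cmp_.group_b_mean,
                f"{groups[1]}_sd": cmp_.group_b_sd,
                "p_between_groups": cmp_.p_value,
            })
    table1 = pd.DataFrame(rows1)

    # ---- table 2: pre-contrast T1 by layer ----------------------------
    layers = df[df["layer"].isin(["superficial", "deep"])].copy()
    if pool_compartments:
        layers = (
            layers.groupby(["subject_id", "group", "segment", "layer"],
                           as_index=False)
            .agg({"t1pre_ms": "mean", "gd_mM": "mean"})
            .assign(compartment="pooled")
        )
    rows2 = []
    for segment in ("NWB", "WB"):
        for compartment in sorted(layers["compartment"].unique()):
            block = layers[(layers["segment"] == segment)
                           & (layers["compartment"] == compartment)]
            for layer in ("superficial", "deep"):
                sub = block[block["layer"] == layer]
                cmp_ = _describe_and_test(sub, "t1pre_ms", groups,
                                          f"{segment} {compartment} {layer}")
                if cmp_ is None:
                    continue
                rows2.append({
                    "segment": segment, "compartment": compartment,
                    "layer": layer,
                    f"{groups[0]}_mean": cmp_.group_a_mean,
                    f"{groups[0]}_sd": cmp_.group_a_sd,
                    f"{groups[1]}_mean": cmp_.group_b_mean,
                    f"{groups[1]}_sd": cmp_.group_b_sd,
                    "p_between_groups": cmp_.p_value,
                })
            for g in groups:
                rows2.append({
                    "segment": segment, "compartment": compartment,
                    "layer": "superficial_vs_deep",
                    "group": g,
                    "p_paired": _paired_p(
                        block[block["group"] == g], "t1pre_ms",
                        "layer", ("superficial", "deep")),
                })
    table2 = pd.DataFrame(rows2)

    # ---- table 3: superficial [Gd] ------------------------------------
    sup = df[df["layer"] == "superficial"].copy()
    if pool_compartments:
        sup = (
            sup.groupby(["subject_id", "group", "segment"], as_index=False)
            .agg({"gd_mM": "mean"})
            .assign(compartment="pooled")
        )
    rows3 = []
    for segment in ("NWB", "WB"):
        for compartment in sorted(sup["compartment"].unique()):
            sub = sup[(sup["segment"] == segment)
                      & (sup["compartment"] == compartment)]
            cmp_ = _describe_and_test(sub, "gd_mM", groups,
                                      f"{segment} {compartment} superficial gd")
            if cmp_ is None:
                continue
            rows3.append({
                "segment": segment, "compartment": compartment,
                f"{groups[0]}_mean": cmp_.group_a_mean,
                f"{groups[0]}_sd": cmp_.group_a_sd,
                f"{groups[1]}_mean": cmp_.group_b_mean,
                f"{groups[1]}_sd": cmp_.group_b_sd,
                "p_between_groups": cmp_.p_value,
            })
    for compartment in sorted(sup["compartment"].unique()):
        block = sup[sup["compartment"] == compartment]
        for g in groups:
            rows3.append({
                "segment": "NWB_vs_WB", "compartment": compartment,
                "group": g,
                "p_paired": _paired_p(block[block["group"] == g], "gd_mM",
                                      "segment", ("NWB", "WB")),
            })
    table3 = pd.DataFrame(rows3)
    return {"table1": table1, "table2": table2, "table3": table3}


def confound_analysis(summaries: pd.DataFrame,
                      min_observations: int = 10) -> dict[str, CorrelationResult]:
    """Thickness-confounding correlations pooled over all segments.

    Three Spearman correlations of segment thickness against (a) the bulk
    BMI-corrected dGEMRIC index, (b) the superficial-layer [Gd], (c) the
    deep-layer [Gd].  A thick cartilage retains an unenhanced deep zone at
    the imaging delay, so with homogeneous tissue the bulk index and the
    deep concentration depend on thickness while the superficial
    concentration does not.
    """
    full = summaries[summaries["layer"] == "full"].dropna(
        subset=["thickness_mm", "index_ms"])
    sup = summaries[summaries["layer"] == "superficial"].dropna(
        subset=["thickness_mm", "gd_mM"])
    deep = summaries[summaries["layer"] == "deep"].dropna(
        subset=["thickness_mm", "gd_mM"])
    for name, block in (("full", full), ("superficial", sup), ("deep", deep)):
        if len(block) < min_observations:
            raise ValueError(
                f"{name}-layer block has {len(block)} observations; "
                f"at least {min_observations} required"
            )
    return {
        "rho_thickness_index": spearman(full["thickness_mm"], full["index_ms"]),
        "rho_thickness_gd_superficial": spearman(sup["thickness_mm"], sup["gd_mM"]),
        "rho_thickness_gd_deep": spearman(deep["thickness_mm"], deep["gd_mM"]),
    }
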