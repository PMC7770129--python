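"""Property classification rules and group statistics for NBE analyses.

This layer relates per-molecule NBE scores to experimental property tables:

* qualitative water-solubility terms are mapped to soluble / insoluble /
  unclassified groups by exact-phrase matching against two fixed term lists;
* human intestinal absorption (HIA) is dichotomized at a fraction-absorbed
  (FA%) threshold of 30% into HIA+ (absorbable) and HIA- (nonabsorbable);
* Spearman rank correlation (midranks under ties), two-group tests (Welch's
  t by default, or the two-sample Mann-Whitney rank-sum), and classical
  one-way ANOVA compare NBE across property-defined groups.

All tests are two-sided and report raw p-values; no multiple-testing
correction is applied. Missing values are dropped pairwise, never imputed.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ArgumentError,
    DegenerateDataError,
    InputError,
    InsufficientDataError,
)
from .nbe_core import NBEResult

logger = logging.getLogger(__name__)


class SolubilityClass(str, enum.Enum):
    SOLUBLE = "soluble"
    INSOLUBLE = "insoluble"
    UNCLASSIFIED = "unclassified"


class HIAClass(str, enum.Enum):
    HIA_PLUS = "HIA+"
    HIA_MINUS = "HIA-"


# Exact qualitative solubility phrases assigned to each group. Terms not on
# either list (e.g. "slightly soluble") stay unclassified rather than being
# guessed. Longest phrases are matched first so "poorly soluble" can never be
# claimed by its "soluble" suffix.
INSOLUBLE_TERMS = (
    "insoluble",
    "almost insoluble",
    "low soluble",
    "mostly insoluble",
    "non-soluble",
    "not soluble",
    "poorly soluble",
)
SOLUBLE_TERMS = (
    "soluble",
    "easily soluble",
    "completely soluble",
    "freely soluble",
    "highly soluble",
    "very soluble",
)

HIA_FA_THRESHOLD = 30.0  # FA% cutoff separating absorbable from nonabsorbable

_TERM_MAP = {term: SolubilityClass.INSOLUBLE for term in INSOLUBLE_TERMS}
_TERM_MAP.update({term: SolubilityClass.SOLUBLE for term in SOLUBLE_TERMS})
# Ordered longest-first: exact-phrase matching over this sequence guarantees
# a multiword term is preferred over any of its substrings.
_TERMS_BY_LENGTH = sorted(_TERM_MAP, key=len, reverse=True)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation output: rho in [-1, 1], two-sided p, n pairs."""

    rho: float
    p_value: float
    n: int
    n_dropped: int = 0


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a group-difference test.

    ``test_name`` is one of t_test / wilcoxon / anova; ``statistic`` is the
    Welch t, the Mann-Whitney U of the first group, or the one-way F.
    """

    test_name: Literal["t_test", "wilcoxon", "anova"]
    group_labels: tuple[str, ...]
    group_ns: tuple[int, ...]
    group_means: tuple[float, ...]
    statistic: float
    p_value: float


def classify_solubility(term: str) -> SolubilityClass:
    """Map a free-text solubility description onto soluble / insoluble /
    unclassified by case-insensitive exact-phrase match, preferring the
    longest matching phrase."""
    normalized = " ".join(str(term).lower().split())
    for phrase in _TERMS_BY_LENGTH:
        if normalized == phrase:
            return _TERM_MAP[phrase]
    return SolubilityClass.UNCLASSIFIED


def classify_hia(fa_percent: float) -> HIAClass:
    """Dichotomize fraction absorbed (FA%, 0-100) at 30%: >= 30 is HIA+."""
    fa = float(fa_percent)
    if not math.isfinite(fa) or not 0 <= fa <= 100:
        raise ArgumentError(f"FA% must be a finite percentage in [0, 100], got {fa_percent!r}")
    return HIAClass.HIA_PLUS if fa >= HIA_FA_THRESHOLD else HIAClass.HIA_MINUS


def _clean_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray, int]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ArgumentError("x and y must be 1-D sequences of equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    return xa[keep], ya[keep], int((~keep).sum())


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties, two-sided p-value.

    Requires at least 3 pairwise-complete observations; a constant input
    vector raises :class:`DegenerateDataError` (rho is undefined, not 0).
    """
    xa, ya, n_dropped = _clean_pairs(x, y)
    if xa.size < 3:
        raise InsufficientDataError(f"spearman needs >= 3 complete pairs, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("spearman is undefined for a constant vector")
    res = stats.spearmanr(xa, ya)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue),
                             n=int(xa.size), n_dropped=n_dropped)


def _group_summary(groups: Sequence[np.ndarray], labels: Sequence[str]) -> dict:
    return dict(
        group_labels=tuple(str(l) for l in labels),
        group_ns=tuple(int(g.size) for g in groups),
        group_means=tuple(float(g.mean()) for g in groups),
    )


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    kind: Literal["t_test", "wilcoxon"] = "t_test",
    equal_var: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``t_test`` is Welch's unequal-variance t by default (``equal_var=True``
    restores Student's t). ``wilcoxon`` is the two-sample Mann-Whitney
    rank-sum: exact null distribution when both groups have <= 8
    observations and there are no ties, otherwise the normal approximation
    with midranks, tie correction and continuity correction.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    aa = aa[np.isfinite(aa)]
    bb = bb[np.isfinite(bb)]

    if kind == "t_test":
        if aa.size < 2 or bb.size < 2:
            raise InsufficientDataError("t-test needs >= 2 observations per group")
        if np.ptp(aa) == 0 and np.ptp(bb) == 0:
            raise DegenerateDataError("t-test undefined: zero variance in both groups")
        res = stats.ttest_ind(aa, bb, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
    elif kind == "wilcoxon":
        if aa.size < 1 or bb.size < 1 or aa.size + bb.size < 4:
            raise InsufficientDataError("wilcoxon needs n >= 1 per group and combined n >= 4")
        pooled = np.concatenate([aa, bb])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (not has_ties and max(aa.size, bb.size) <= 8) else "asymptotic"
        res = stats.mannwhitneyu(aa, bb, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ArgumentError(f"kind must be 't_test' or 'wilcoxon', got {kind!r}")

    return GroupComparison(
        test_name=kind, statistic=stat, p_value=p,
        **_group_summary([aa, bb], labels),
    )


def anova_oneway(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> GroupComparison:
    """Classical one-way fixed-effects ANOVA over three or more groups."""
    if len(groups) < 3:
        raise ArgumentError(
            f"anova_oneway needs >= 3 groups, got {len(groups)}; use two_group_test for 2"
        )
    arrays = []
    for g in groups:
        ga = np.asarray(g, dtype=float)
        ga = ga[np.isfinite(ga)]
        if ga.size < 2:
            raise InsufficientDataError("each ANOVA group needs >= 2 observations")
        arrays.append(ga)
    if labels is None:
        labels = [f"group_{i + 1}" for i in range(len(arrays))]
    res = stats.f_oneway(*arrays)
    return GroupComparison(
        test_name="anova", statistic=float(res.statistic), p_value=float(res.pvalue),
        **_group_summary(arrays, labels),
    )


def load_property_table(path: str | Path) -> pd.DataFrame:
    """Load a delimited property table with an ``id`` column.

    Delimiter (comma/tab) is auto-detected; ``#`` comment lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"property table not found: {path}")
    with path.open() as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"id": str})
    if "id" not in df.columns:
        raise InputError(f"{path}: property table must have an 'id' column")
    return df


def correlate_nbe_with_property(
    results: Sequence[NBEResult],
    table: pd.DataFrame,
    property_name: str,
) -> CorrelationResult:
    """Join NBE results to a property column on molecule id and correlate.

    Incomplete pairs (missing ids or non-finite property values) are
    dropped and counted in ``n_dropped``; fewer than 3 surviving pairs
    raise :class:`InsufficientDataError`.
    """
    if property_name not in table.columns:
        raise ArgumentError(f"property {property_name!r} not in table columns {list(table.columns)}")
    nbe_df = pd.DataFrame({"id": [r.id for r in results], "nbe": [r.nbe for r in results]})
    prop = table[["id", property_name]].copy()
    prop[property_name] = pd.to_numeric(prop[property_name], errors="coerce")
    joined = nbe_df.merge(prop, on="id", how="inner")
    n_total = len(nbe_df)
    complete = joined.dropna(subset=["nbe", property_name])
    n_dropped = n_total - len(complete)
    if n_dropped:
        logger.info("correlate: dropped %d of %d molecules (unjoined or missing %r)",
                    n_dropped, n_total, property_name)
    if len(complete) < 3:
        raise InsufficientDataError(
            f"need >= 3 joined pairs for {property_name!r}, got {len(complete)}"
        )
    res = spearman(complete["nbe"].to_numpy(), complete[property_name].to_numpy())
    return CorrelationResult(rho=res.rho, p_value=res.p_value, n=res.n,
                             n_dropped=n_dropped + res.n_dropped)
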