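"""Reliable-detection filtering, detection-set overlap, RNA-type composition.

A feature is "reliably detected" in a fraction when it has at least
``min_reads`` mapped reads in strictly more than ``min_sample_share`` of that
fraction's samples; filtering happens on raw counts, before normalization.
Detection sets are compared across fractions as a Venn summary, and per-sample
RNA-type read proportions are compared between fractions with a rank-based
two-sample test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .io import ConfigError, CountMatrix, DataError


def filter_reliable(counts: CountMatrix, min_reads: int = 5, min_sample_share: float = 0.5) -> CountMatrix:
    """Keep features with >= min_reads in strictly more than min_sample_share of samples.

    The boundary is strict: a feature meeting the read threshold in exactly
    half the samples (12 of 24 at the default share) is removed. Columns are
    never touched.
    """
    if min_reads <= 0 or min_sample_share <= 0:
        raise ConfigError("filter thresholds must be positive")
    n_samples = counts.counts.shape[1]
    if counts.counts.empty:
        warnings.warn("filtering an empty count matrix", stacklevel=2)
        return counts
    n_detected = (counts.counts >= min_reads).sum(axis=1)
    keep = counts.counts.index[n_detected > min_sample_share * n_samples]
    return counts.subset_features(keep)


@dataclass
class VennSummary:
    """Detection sets per fraction with all intersection cardinalities."""

    sets: dict[str, set[str]]
    region_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fractions = sorted(self.sets)
        for r in range(1, len(fractions) + 1):
            for combo in itertools.combinations(fractions, r):
                common = set.intersection(*(self.sets[f] for f in combo))
                self.region_sizes["&".join(combo)] = len(common)
        self.region_sizes["union"] = len(set.union(*self.sets.values()))

    @property
    def union_size(self) -> int:
        return self.region_sizes["union"]

    def to_dict(self) -> dict:
        return {"set_sizes": {f: len(s) for f, s in self.sets.items()}, "regions": dict(self.region_sizes)}


def detection_sets(filtered: dict[str, CountMatrix | set]) -> VennSummary:
    """Exact per-fraction detection sets and their overlaps.

    Feature identifiers must be comparable across fractions: a feature carrying
    conflicting RNA-type annotations in two fractions indicates mismatched
    universes and raises :class:`DataError`.
    """
    if len(filtered) < 2:
        raise ConfigError("need at least two fractions to compare detection sets")
    sets: dict[str, set[str]] = {}
    seen_types: dict[str, str] = {}
    for frac, value in filtered.items():
        if isinstance(value, CountMatrix):
            sets[frac] = set(value.features)
            for feat, rna_type in value.feature_types.items():
                if seen_types.setdefault(feat, rna_type) != rna_type:
                    raise DataError(f"feature {feat!r} annotated inconsistently across fractions")
        else:
            sets[frac] = set(value)
    return VennSummary(sets=sets)


@dataclass
class CompositionTable:
    """Per-sample RNA-type read proportions and between-fraction comparisons."""

    per_sample: pd.DataFrame  # rows samples, proportion columns per type + fraction
    fraction_means: pd.DataFrame  # rows fractions, columns types
    comparisons: pd.DataFrame  # rna_type, fraction_a, fraction_b, p_value


def _rank_test(a, b) -> float:
    pooled = list(a) + list(b)
    if len(set(pooled)) == 1:  # degenerate: no variation at all
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def composition_summary(counts: dict[str, CountMatrix]) -> CompositionTable:
    """Read-share of each RNA type per sample, averaged per fraction, compared pairwise.

    Comparisons use a two-sided Mann-Whitney rank test on the per-sample
    proportions; fractions with a single sample are summarized but excluded
    from testing (with a warning).
    """
    rows = []
    for frac, cm in counts.items():
        totals = cm.counts.sum(axis=0)
        if (totals == 0).any():
            raise DataError(f"zero-total sample in fraction {frac!r}")
        by_type = cm.counts.groupby(cm.feature_types).sum()
        props = (by_type / totals).T  # samples x types
        props["fraction"] = frac
        rows.append(props)
    per_sample = pd.concat(rows).fillna(0.0)

    type_cols = [c for c in per_sample.columns if c != "fraction"]
    fraction_means = per_sample.groupby("fraction")[type_cols].mean()

    comparisons = []
    testable = [f for f in counts if (per_sample["fraction"] == f).sum() >= 2]
    skipped = sorted(set(counts) - set(testable))
    if skipped:
        warnings.warn(f"fractions with a single sample excluded from comparison: {skipped}", stacklevel=2)
    for fa, fb in itertools.combinations(testable, 2):
        a_rows = per_sample[per_sample["fraction"] == fa]
        b_rows = per_sample[per_sample["fraction"] == fb]
        for rna_type in type_cols:
            comparisons.append(
                {
                    "rna_type": rna_type,
                    "fraction_a": fa,
                    "fraction_b": fb,
                    "p_value": _rank_test(a_rows[rna_type].to_numpy(), b_rows[rna_type].to_numpy()),
                }
            )
    comp_df = pd.DataFrame(comparisons, columns=["rna_type", "fraction_a", "fraction_b", "p_value"])
    return CompositionTable(per_sample=per_sample, fraction_means=fraction_means, comparisons=comp_df)
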