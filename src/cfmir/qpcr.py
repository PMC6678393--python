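"""Sequencing-guided qPCR reference selection, delta-Cq normalization, testing.

Reference assays are picked from the sequencing data: features whose
between-group fold-change stays under 1.1 with p > 0.05 in every plasma
fraction and whose within-group coefficient of variation of TMM-normalized
counts stays under 0.05, ranked by abundance. Cq values are normalized against
the arithmetic mean of the reference Cqs (the geometric mean of the
linear-scale quantities), giving delta-Cq = Cq(target) - mean(Cq(refs)); one
cycle corresponds to a two-fold quantity change. Group differences are tested
with Welch's unequal-variance t-test on -delta-Cq, and platform concordance is
reported as the share of features whose sequencing and qPCR fold-changes agree
in direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigError, DataError


@dataclass
class ReferenceSet:
    """Selected normalizer assays plus per-candidate selection diagnostics."""

    members: list[str]  # sorted by descending abundance
    diagnostics: pd.DataFrame

    def to_dict(self) -> dict:
        return {"members": list(self.members)}


def _symmetric_fc(fc: pd.Series) -> pd.Series:
    return np.maximum(fc, 1.0 / fc)


def select_reference_mirnas(
    de_results: dict[str, pd.DataFrame],
    norm_counts: dict[str, pd.DataFrame],
    groups: dict[str, pd.Series],
    fc_max: float = 1.1,
    p_min: float = 0.05,
    cv_max: float = 0.05,
    k: int = 4,
) -> ReferenceSet:
    """Pick k stable, abundant features to serve as qPCR normalizers.

    A candidate must satisfy max(FC, 1/FC) < fc_max and p > p_min in every
    fraction, and CV < cv_max within each group of each fraction (CV on
    TMM-normalized counts). Survivors are ranked by their mean normalized
    abundance over all samples of all fractions; the top k are returned.
    Fewer than k candidates yields all of them with a warning.
    """
    fractions = list(de_results)
    if not fractions:
        raise ConfigError("no fractions supplied")
    candidates = set.intersection(*(set(de_results[f].index) for f in fractions))
    for f in fractions:
        candidates &= set(norm_counts[f].index)

    rows = []
    for feat in sorted(candidates):
        row: dict[str, float | str | bool] = {"feature": feat}
        passes = True
        abundances = []
        for f in fractions:
            de = de_results[f]
            fc = float(de.loc[feat, "fold_change"])
            p = float(de.loc[feat, "p_value"])
            sym = max(fc, 1.0 / fc)
            row[f"fc_{f}"] = sym
            row[f"p_{f}"] = p
            passes &= (sym < fc_max) and (p > p_min)
            counts = norm_counts[f].loc[feat]
            abundances.append(float(counts.mean()))
            g = groups[f].reindex(counts.index)
            for level in g.unique():
                vals = counts[(g == level).to_numpy()]
                mean = float(vals.mean())
                cv = float(vals.std(ddof=1) / mean) if mean > 0 else np.inf
                row[f"cv_{f}_{level}"] = cv
                passes &= cv < cv_max
        row["mean_abundance"] = float(np.mean(abundances))
        row["passes"] = passes
        rows.append(row)

    diag = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame()
    passing = diag[diag["passes"]].sort_values("mean_abundance", ascending=False) if len(diag) else diag
    members = list(passing.index[:k])
    if len(members) < k:
        warnings.warn(f"only {len(members)} reference candidates pass (requested {k})", stacklevel=2)
    return ReferenceSet(members=members, diagnostics=diag)


@dataclass
class NormalizedQuantity:
    """Per-sample delta-Cq and linear relative quantity per assay."""

    delta_cq: pd.DataFrame  # samples x assays
    rel_quantity: pd.DataFrame  # 2^(-delta_cq)
    references: list[str]


def normalize_cq(cq: pd.DataFrame, refs: ReferenceSet | list[str]) -> NormalizedQuantity:
    """delta-Cq against the mean reference Cq of each sample.

    The per-sample normalizer is the arithmetic mean of the reference Cqs —
    equivalently the geometric mean of the linear-scale reference quantities.
    Samples missing any reference Cq are dropped with a warning.
    """
    members = refs.members if isinstance(refs, ReferenceSet) else list(refs)
    missing = [m for m in members if m not in cq.columns]
    if missing:
        raise DataError(f"reference assay(s) absent from Cq table: {missing}")
    ref_block = cq[members]
    bad = ref_block.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} sample(s) with missing reference Cq", stacklevel=2)
    kept = cq.loc[~bad]
    ref_term = kept[members].mean(axis=1)
    delta = kept.sub(ref_term, axis=0)
    return NormalizedQuantity(delta_cq=delta, rel_quantity=2.0 ** (-delta), references=members)


def welch_test(norm: NormalizedQuantity, groups: pd.Series,
               numerator: str = "PTSD+", denominator: str = "PTSD-") -> pd.DataFrame:
    """Welch's two-sided t-test per assay on -delta-Cq (log2 quantities).

    Fold-change = 2^(mean(-dCq, numerator) - mean(-dCq, denominator));
    Satterthwaite degrees of freedom. Two groups of constant equal values get
    p = 1.
    """
    g = groups.reindex(norm.delta_cq.index)
    rows = []
    for assay in norm.delta_cq.columns:
        neg_dcq = -norm.delta_cq[assay].dropna()
        ga = g.reindex(neg_dcq.index)
        a = neg_dcq[(ga == numerator).to_numpy()].to_numpy(dtype=float)
        b = neg_dcq[(ga == denominator).to_numpy()].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise DataError(f"assay {assay!r}: need >= 2 samples per group")
        diff = a.mean() - b.mean()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if diff == 0 else 0.0
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "assay": assay,
                "fold_change": 2.0**diff,
                "log2_fold_change": diff,
                "t": float(t),
                "p_value": float(p),
                "n_num": len(a),
                "n_den": len(b),
            }
        )
    return pd.DataFrame(rows).set_index("assay")


def concordance(seq_de: pd.DataFrame, qpcr_results: pd.DataFrame,
                p_cutoff: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Direction agreement of sequencing and qPCR fold-changes per feature.

    Returns the per-feature report (sign agreement and both-significant flag)
    and the overall share of direction-concordant features.
    """
    shared = seq_de.index.intersection(qpcr_results.index)
    if len(shared) == 0:
        raise DataError("no overlapping features between sequencing and qPCR results")
    seq_l2fc = seq_de.loc[shared, "log2_fold_change"].to_numpy(dtype=float)
    q_l2fc = qpcr_results.loc[shared, "log2_fold_change"].to_numpy(dtype=float)
    agree = np.sign(seq_l2fc) * np.sign(q_l2fc) > 0
    both_sig = (
        (seq_de.loc[shared, "p_value"].to_numpy() < p_cutoff)
        & (qpcr_results.loc[shared, "p_value"].to_numpy() < p_cutoff)
    )
    report = pd.DataFrame(
        {
            "seq_log2_fc": seq_l2fc,
            "qpcr_log2_fc": q_l2fc,
            "direction_agrees": agree,
            "both_significant": both_sig,
        },
        index=shared,
    )
    return report, float(agree.mean())
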