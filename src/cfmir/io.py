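"""Shared containers and plain-text readers/writers.

All interchange formats are plain text: counts and sample tables as TSV,
mature sequences as FASTA, term sets as GMT, miRNA-target interactions as
two-column TSV, Cq tables as CSV, and ground truth / summaries as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FRACTIONS = ("WP", "EV", "EVD")
GROUPS = ("PTSD-", "PTSD+")

RNA_TYPES = ("miRNA", "piRNA", "lncRNA", "snoRNA", "rRNA", "tRNA", "misc")


class ConfigError(ValueError):
    """Invalid configuration or thresholds (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass
class CountMatrix:
    """Feature-by-sample table of nonnegative integer read counts.

    ``counts`` rows are features, columns samples. ``feature_types`` maps each
    feature to its small-RNA class (miRNA, piRNA, ...). ``samples`` carries one
    row per sample with ``subject``, ``group`` (PTSD+/PTSD-) and ``fraction``
    (WP, EV, EVD) columns.
    """

    counts: pd.DataFrame
    feature_types: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("count matrix contains negative entries")
        if self.counts.index.has_duplicates:
            raise DataError("feature identifiers are not unique")
        missing = self.counts.index.difference(self.feature_types.index)
        if len(missing):
            raise DataError(f"features without rna_type annotation: {list(missing)[:5]}")
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise DataError(f"samples without metadata: {list(missing)[:5]}")
        self.counts = self.counts.rename_axis(index="feature", columns=None)
        self.feature_types = self.feature_types.reindex(self.counts.index)
        self.samples = self.samples.reindex(self.counts.columns)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_features(self, keep) -> "CountMatrix":
        keep = [f for f in self.counts.index if f in set(keep)]
        return CountMatrix(self.counts.loc[keep], self.feature_types.loc[keep], self.samples)

    def subset_samples(self, keep) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s in set(keep)]
        return CountMatrix(self.counts[keep], self.feature_types, self.samples.loc[keep])

    def groups(self) -> pd.Series:
        return self.samples["group"]


@dataclass
class InteractionDB:
    """miRNA-target interactions plus flat term (GO-BP / pathway) gene sets.

    The annotation universe is the set of genes appearing in any term — the
    denominator ``d`` of the fold-enrichment score.
    """

    targets: dict[str, set[str]]
    terms: dict[str, set[str]]
    term_categories: dict[str, str] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# counts / sample tables (TSV)
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.insert(0, "rna_type", cm.feature_types)
    df.to_csv(path, sep="\t", index_label="feature")


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="feature")
    rna_type = df.pop("rna_type")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    keep = [s for s in samples.index if s in df.columns]  # sample table may span fractions
    if not keep:
        raise DataError("no sample in the metadata table matches the count columns")
    return CountMatrix(df[keep].astype(int), rna_type, samples.loc[keep])


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# sequences (FASTA)
# ---------------------------------------------------------------------------

def write_fasta(sequences: pd.Series, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> pd.Series:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return pd.Series(records, dtype=object)


# ---------------------------------------------------------------------------
# annotation tables (GMT, two-column TSV)
# ---------------------------------------------------------------------------

def write_gmt(terms: dict[str, set[str]], path: str | Path, categories: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (categories or {}).get(term, "na")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    terms: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms[fields[0]] = set(fields[2:])
            categories[fields[0]] = fields[1]
    return terms, categories


def write_interactions(targets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_interactions(path: str | Path) -> dict[str, set[str]]:
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            targets.setdefault(fields[0], set()).add(fields[1])
    return targets


def read_interaction_db(interactions_path: str | Path, gmt_path: str | Path) -> InteractionDB:
    targets = read_interactions(interactions_path)
    terms, categories = read_gmt(gmt_path)
    return InteractionDB(targets=targets, terms=terms, term_categories=categories)


# ---------------------------------------------------------------------------
# Cq tables (CSV) and JSON payloads
# ---------------------------------------------------------------------------

def write_cq(cq: pd.DataFrame, path: str | Path) -> None:
    cq.to_csv(path, index_label="sample")


def read_cq(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")


def write_json(payload, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (set, frozenset, tuple)):
            return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        if hasattr(obj, "item"):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
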