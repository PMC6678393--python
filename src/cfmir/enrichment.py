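"""miRNA target retrieval, term overrepresentation, and fold-enrichment scores.

Term enrichment of a target-gene set is one-sided hypergeometric
overrepresentation on the 2x2 table (gene set x term membership over the
annotation universe); terms pass at p < 0.1 with at least 3 target genes.

The fold-enrichment score (FES) of a miRNA for a term is

    FES = (a / b) / (c / d)

with a = the miRNA's targets inside the term, b = the miRNA's targets inside
the annotation universe, c = the term's genes, and d = all genes appearing in
any term. A focal miRNA's association with a term is judged against the
empirical background: the share of non-altered miRNAs whose FES for the same
term strictly exceeds the focal FES (flagged when below 5%).
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import ConfigError, DataError, InteractionDB


def get_targets(mirna: str, db: InteractionDB) -> set[str]:
    """The stored target-gene set of one miRNA (exact, deterministic)."""
    try:
        return set(db.targets[mirna])
    except KeyError:
        near = difflib.get_close_matches(mirna, db.targets.keys(), n=3)
        raise DataError(f"unknown miRNA {mirna!r}; similar identifiers: {near}") from None


def enrich_terms(genes, db: InteractionDB, p_cutoff: float = 0.1, min_overlap: int = 3,
                 ease: bool = False) -> pd.DataFrame:
    """Hypergeometric overrepresentation of every term in a gene set.

    Genes outside the annotation universe are dropped with a warning. With
    ``ease=True`` one overlapping gene is discounted before taking the tail
    (the conservative EASE-style variant); default is the plain tail.
    Selection: p < p_cutoff and overlap >= min_overlap.
    """
    genes = set(genes)
    universe = db.universe
    outside = genes - universe
    if outside:
        warnings.warn(f"{len(outside)} gene(s) outside the annotation universe dropped", stacklevel=2)
    genes &= universe
    if not genes:
        return pd.DataFrame(
            columns=["overlap", "set_size", "term_size", "universe_size",
                     "p_value", "fold_enrichment", "category", "selected"]
        )
    n_universe = len(universe)
    n_set = len(genes)
    rows = []
    for term, term_genes in db.terms.items():
        overlap = len(genes & term_genes)
        k = max(overlap - 1, 0) if ease and overlap > 0 else overlap
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(term_genes), n_set)) if overlap > 0 else 1.0
        fold = (overlap / n_set) / (len(term_genes) / n_universe)
        rows.append(
            {
                "term": term,
                "overlap": overlap,
                "set_size": n_set,
                "term_size": len(term_genes),
                "universe_size": n_universe,
                "p_value": min(p, 1.0),
                "fold_enrichment": fold,
                "category": db.term_categories.get(term, "na"),
                "selected": (p < p_cutoff) and (overlap >= min_overlap),
            }
        )
    return pd.DataFrame(rows).set_index("term").sort_values("p_value")


@dataclass
class FESRecord:
    """Fold-enrichment score of one miRNA for one term, with its 2x2 counts."""

    mirna: str
    term: str
    a: int  # miRNA targets inside the term
    b: int  # miRNA targets inside the annotation universe
    c: int  # genes in the term
    d: int  # genes in the annotation universe
    fes: float
    background_percentile: float | None = None
    top5: bool | None = None


def fes(mirna: str, term: str, db: InteractionDB, _universe: set[str] | None = None) -> FESRecord:
    """FES = (a/b) / (c/d) for one miRNA-term pair.

    A miRNA with no targets inside the annotation universe (b = 0) has no
    defined score and raises :class:`DataError`.
    """
    if term not in db.terms:
        raise DataError(f"unknown term {term!r}")
    universe = db.universe if _universe is None else _universe
    targets = get_targets(mirna, db) & universe
    b = len(targets)
    if b == 0:
        raise DataError(f"miRNA {mirna!r} has no annotated targets in the universe")
    term_genes = db.terms[term]
    a = len(targets & term_genes)
    c = len(term_genes)
    d = len(universe)
    if c == 0 or d == 0:
        raise DataError(f"term {term!r} or universe is empty")
    return FESRecord(mirna=mirna, term=term, a=a, b=b, c=c, d=d,
                     fes=(a / b) / (c / d))


def fes_background(mirna: str, terms, db: InteractionDB,
                   exclude=(), top_share: float = 0.05) -> list[FESRecord]:
    """FES of a focal miRNA for each term, with its empirical background percentile.

    The background is every miRNA in the database except the focal one and the
    ``exclude`` list (miRNAs altered between groups). The percentile is the
    share of background miRNAs whose FES for the term strictly exceeds the
    focal miRNA's; records with percentile below ``top_share`` carry the
    ``top5`` flag. Background miRNAs with no annotated targets are skipped.
    """
    background = [m for m in db.targets if m != mirna and m not in set(exclude)]
    if not background:
        raise ConfigError("empty background miRNA set")
    universe = db.universe
    records = []
    for term in terms:
        if term not in db.terms:
            warnings.warn(f"term {term!r} absent from database; skipped", stacklevel=2)
            continue
        focal = fes(mirna, term, db, _universe=universe)
        higher = 0
        n_bg = 0
        for other in background:
            try:
                rec = fes(other, term, db, _universe=universe)
            except DataError:
                continue
            n_bg += 1
            if rec.fes > focal.fes:
                higher += 1
        if n_bg == 0:
            raise ConfigError("no background miRNA has annotated targets")
        focal.background_percentile = higher / n_bg
        focal.top5 = focal.background_percentile < top_share
        records.append(focal)
    return records


def fes_records_frame(records: list[FESRecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna": r.mirna, "term": r.term, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "fes": r.fes, "background_percentile": r.background_percentile, "top5": r.top5,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["mirna", "term", "a", "b", "c", "d",
                                       "fes", "background_percentile", "top5"])
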