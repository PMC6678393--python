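"""Synthetic cohort generator for cell-free small-RNA studies.

Emulates a three-fraction plasma design — whole plasma (WP), extracellular
vesicles (EV) and EV-depleted plasma (EVD) — profiled in two groups (PTSD+ /
PTSD-) of matched subjects. Counts are negative-binomial with a log-normal
baseline abundance spectrum, fraction-specific RNA-type composition (miRNA
dominates plasma/EVD reads, a minority of EV reads), planted group effects,
and designated stable reference miRNAs. Companion generators produce mature
sequences with planted 3'-end sorting motifs, a miRNA-target / term annotation
database with planted fold-enrichment, and correlated qPCR Cq tables.

Every generator is deterministic given its seed, and the ground truth needed
to score recovery downstream is returned alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FRACTIONS, GROUPS, ConfigError, CountMatrix, InteractionDB

#: default per-fraction read composition by RNA type; miRNA carries ~80% of
#: reads in whole plasma and EVD but only ~33% in EV, where other small-RNA
#: classes (piRNA, lncRNA, rRNA, tRNA) take a far larger share.
DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "WP": {"miRNA": 0.80, "piRNA": 0.03, "lncRNA": 0.04, "snoRNA": 0.02, "rRNA": 0.05, "tRNA": 0.04, "misc": 0.02},
    "EV": {"miRNA": 0.33, "piRNA": 0.15, "lncRNA": 0.14, "snoRNA": 0.08, "rRNA": 0.15, "tRNA": 0.10, "misc": 0.05},
    "EVD": {"miRNA": 0.80, "piRNA": 0.03, "lncRNA": 0.04, "snoRNA": 0.02, "rRNA": 0.05, "tRNA": 0.04, "misc": 0.02},
}

DEFAULT_N_OTHER = {"piRNA": 60, "lncRNA": 40, "snoRNA": 30, "rRNA": 20, "tRNA": 20, "misc": 20}

MOTIFS = ("GGAG", "GGCU")


@dataclass
class PlantedEffect:
    """A group effect planted on one feature in one fraction.

    ``fold_change`` > 0 is the PTSD+/PTSD- abundance ratio after applying
    ``direction`` ("up" keeps it, "down" inverts it).
    """

    feature: str
    fraction: str
    fold_change: float
    direction: str = "up"

    @property
    def multiplier(self) -> float:
        return self.fold_change if self.direction == "up" else 1.0 / self.fold_change


@dataclass
class SimConfig:
    n_per_group: int = 12
    fractions: tuple[str, ...] = FRACTIONS
    n_mirna: int = 300
    n_other_rna: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_OTHER))
    composition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {f: dict(p) for f, p in DEFAULT_COMPOSITION.items()}
    )
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.2
    dispersion: float = 0.1
    de_spec: list[PlantedEffect] = field(default_factory=list)
    n_reference_candidates: int = 6
    reference_dispersion: float = 2e-4
    reference_boost: float = 200.0
    de_abundance_boost: float = 4.0
    baseline_log_sd: float = 1.5
    cq_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ConfigError("n_per_group must be positive")
        if not self.fractions:
            raise ConfigError("fraction list is empty")
        if self.n_mirna < 1 or any(n < 1 for n in self.n_other_rna.values()):
            raise ConfigError("feature counts must be >= 1")
        if self.dispersion < 0 or self.reference_dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        for frac in self.fractions:
            if frac not in self.composition:
                raise ConfigError(f"no composition for fraction {frac!r}")
            total = sum(self.composition[frac].values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"composition of {frac!r} sums to {total}, not 1")
        for eff in self.de_spec:
            if eff.fold_change <= 0:
                raise ConfigError(f"fold-change must be > 0 for {eff.feature}")
            if eff.fraction not in self.fractions:
                raise ConfigError(f"planted effect on unknown fraction {eff.fraction!r}")


@dataclass
class GroundTruth:
    """Planted truth emitted by the simulator, for recovery scoring."""

    true_de: list[PlantedEffect]
    true_lib_factors: dict[str, float]
    true_dispersion: float
    reference_candidates: list[str]
    baseline: dict[str, pd.Series]
    effect: dict[str, pd.Series]
    target_lib_sizes: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "true_de": [
                {"feature": e.feature, "fraction": e.fraction, "fold_change": e.fold_change, "direction": e.direction}
                for e in self.true_de
            ],
            "true_lib_factors": self.true_lib_factors,
            "true_dispersion": self.true_dispersion,
            "reference_candidates": list(self.reference_candidates),
            "baseline": {f: s.to_dict() for f, s in self.baseline.items()},
            "effect": {f: s.to_dict() for f, s in self.effect.items()},
            "target_lib_sizes": self.target_lib_sizes,
        }


def _feature_names(config: SimConfig) -> tuple[list[str], pd.Series]:
    names = [f"miR-sim-{i + 1:04d}" for i in range(config.n_mirna)]
    types = ["miRNA"] * config.n_mirna
    for rna_type, n in config.n_other_rna.items():
        names += [f"{rna_type}-sim-{i + 1:04d}" for i in range(n)]
        types += [rna_type] * n
    return names, pd.Series(types, index=names, name="rna_type")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, Var = mean + phi*mean^2); phi = 0 degenerates to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = phi <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson]
        m = mean[~poisson]
        p = r / (r + m)
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def simulate_cohort(config: SimConfig) -> tuple[dict[str, CountMatrix], pd.DataFrame, GroundTruth]:
    """Generate one count table per plasma fraction plus sample metadata and truth.

    Counts for feature g in sample i are NB with mean
    ``baseline_share[g] * lib_size[i] * fold_change[g]^[group(i) == PTSD+]``
    and dispersion phi (a much smaller phi for the designated reference
    candidates, which are also boosted to high abundance so that stable,
    abundant normalizer assays exist, as they do in real plasma).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, types = _feature_names(config)
    n = config.n_per_group
    subjects = [f"S{i + 1:02d}" for i in range(2 * n)]
    subject_group = {s: GROUPS[i // n] for i, s in enumerate(subjects)}

    ref_candidates = [f"miR-sim-{i + 1:04d}" for i in range(min(config.n_reference_candidates, config.n_mirna))]
    phi = pd.Series(config.dispersion, index=names, dtype=float)
    phi.loc[ref_candidates] = config.reference_dispersion

    # log-normal baseline spectrum, renormalized within each RNA type so that
    # each type's read share matches the fraction's composition profile
    raw = pd.Series(np.exp(rng.normal(0.0, config.baseline_log_sd, len(names))), index=names)
    raw.loc[ref_candidates] *= config.reference_boost
    # planted markers mimic validated assays: well-expressed, safely detectable
    for eff in config.de_spec:
        if eff.feature in raw.index:
            raw.loc[eff.feature] *= config.de_abundance_boost

    sigma2 = math.log1p(config.lib_size_cv**2)
    mu_log = math.log(config.lib_size_mean) - sigma2 / 2

    tables: dict[str, CountMatrix] = {}
    sample_rows = []
    baseline: dict[str, pd.Series] = {}
    effect: dict[str, pd.Series] = {}
    realized_libs: dict[str, float] = {}
    target_libs: dict[str, float] = {}

    for frac in config.fractions:
        share = pd.Series(0.0, index=names)
        for rna_type, prop in config.composition[frac].items():
            mask = types == rna_type
            if not mask.any():
                continue
            share[mask] = raw[mask] / raw[mask].sum() * prop
        baseline[frac] = share

        mult = pd.Series(1.0, index=names)
        for eff in config.de_spec:
            if eff.fraction == frac:
                if eff.feature not in mult.index:
                    raise ConfigError(f"planted effect on unknown feature {eff.feature!r}")
                mult[eff.feature] = eff.multiplier
        effect[frac] = mult

        sample_ids = [f"{s}_{frac}" for s in subjects]
        libs = np.exp(rng.normal(mu_log, math.sqrt(sigma2), len(subjects)))
        group_up = np.array([subject_group[s] == "PTSD+" for s in subjects])

        mean = share.to_numpy()[:, None] * libs[None, :]
        mean = mean * np.where(group_up[None, :], mult.to_numpy()[:, None], 1.0)
        counts = _nb_draw(rng, mean, np.broadcast_to(phi.to_numpy()[:, None], mean.shape))

        cdf = pd.DataFrame(counts, index=names, columns=sample_ids)
        for sid, subj, lib in zip(sample_ids, subjects, libs):
            sample_rows.append({"sample": sid, "subject": subj, "group": subject_group[subj], "fraction": frac})
            target_libs[sid] = float(lib)
            realized_libs[sid] = float(cdf[sid].sum())
        stab = pd.DataFrame(sample_rows).set_index("sample")
        tables[frac] = CountMatrix(cdf, types.copy(), stab.loc[sample_ids])

    samples = pd.DataFrame(sample_rows).set_index("sample")
    gt = GroundTruth(
        true_de=list(config.de_spec),
        true_lib_factors=realized_libs,
        true_dispersion=config.dispersion,
        reference_candidates=ref_candidates,
        baseline=baseline,
        effect=effect,
        target_lib_sizes=target_libs,
    )
    return tables, samples, gt


def simulate_sequences(
    n: int,
    motif_fraction: float,
    seed: int,
    names: list[str] | None = None,
    length_range: tuple[int, int] = (18, 25),
) -> pd.Series:
    """Random mature miRNA sequences with EV-sorting motifs planted at the 3' end.

    Exactly ``round(n * motif_fraction)`` sequences terminate in GGAG or GGCU;
    the remainder are guaranteed motif-free at the 3' end.
    """
    if not 0.0 <= motif_fraction <= 1.0:
        raise ConfigError("motif_fraction must be in [0, 1]")
    if n == 0:
        return pd.Series(dtype=object)
    if names is None:
        names = [f"miR-sim-{i + 1:04d}" for i in range(n)]
    if len(names) != n:
        raise ConfigError("names length must equal n")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    n_motif = round(n * motif_fraction)
    motif_idx = set(rng.choice(n, size=n_motif, replace=False).tolist())

    seqs = {}
    for i, name in enumerate(names):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        if i in motif_idx:
            motif = MOTIFS[int(rng.integers(0, 2))]
            seq = seq[:-4] + motif
        else:
            while seq.endswith(MOTIFS):
                seq = seq[:-4] + "".join(rng.choice(alphabet, size=4))
        seqs[name] = seq
    return pd.Series(seqs, dtype=object)


def simulate_annotations(
    n_mirna: int,
    n_gene: int,
    n_term: int,
    planted: list[tuple[str, str, float]] | None = None,
    seed: int = 0,
    term_size_range: tuple[int, int] | None = None,
    target_size_range: tuple[int, int] | None = None,
) -> InteractionDB:
    """Random miRNA-target interactions and flat term sets with planted enrichment.

    ``planted`` entries are ``(mirna, term, target_fes)``: the miRNA's overlap
    with the term is set to ``round(fes * b * c / d)`` so the realized
    fold-enrichment score lands within 10% of the target (an unreachable
    target raises :class:`ConfigError`). Unplanted target sets are uniform
    draws from the universe, so the background FES distribution centers on 1.
    """
    planted = planted or []
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_gene)]
    term_names = [f"TERM{i + 1:04d}" for i in range(n_term)]
    mirna_names = [f"miR-sim-{i + 1:04d}" for i in range(n_mirna)]

    if term_size_range is None:
        term_size_range = (max(5, n_gene // 20), max(6, n_gene // 8))
    if target_size_range is None:
        target_size_range = (max(5, n_gene // 40), max(6, n_gene // 10))

    terms: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    for j, term in enumerate(term_names):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        terms[term] = set(rng.choice(genes, size=min(size, n_gene), replace=False).tolist())
        categories[term] = "GOBP" if j % 2 == 0 else "pathway"

    # genes not drawn into any term go into a remainder term, so the annotation
    # universe (the FES denominator d) covers all n_gene genes while the drawn
    # term sizes stay exactly as configured
    covered = set().union(*terms.values()) if terms else set()
    leftover = [g for g in genes if g not in covered]
    if leftover:
        terms["TERM_OTHER"] = set(leftover)
        categories["TERM_OTHER"] = "GOBP"

    d = n_gene
    planted_by_mirna: dict[str, tuple[str, float]] = {}
    for mirna, term, fes in planted:
        if fes <= 0:
            raise ConfigError("target FES must be > 0")
        if term not in terms:
            raise ConfigError(f"planted term {term!r} not among generated terms")
        if mirna in planted_by_mirna:
            raise ConfigError(f"multiple planted terms for {mirna!r}")
        planted_by_mirna[mirna] = (term, fes)

    targets: dict[str, set[str]] = {}
    for mirna in mirna_names:
        b = int(rng.integers(target_size_range[0], target_size_range[1] + 1))
        if mirna in planted_by_mirna:
            term, fes = planted_by_mirna[mirna]
            term_genes = sorted(terms[term])
            c = len(term_genes)
            a = round(fes * b * c / d)
            if a > min(b, c) or a < 1 or abs(a * d / (b * c) / fes - 1.0) > 0.10:
                raise ConfigError(
                    f"target FES {fes} infeasible for {mirna!r}/{term!r} (b={b}, c={c}, d={d})"
                )
            inside = rng.choice(term_genes, size=a, replace=False).tolist()
            outside_pool = sorted(set(genes) - terms[term])
            outside = rng.choice(outside_pool, size=b - a, replace=False).tolist()
            targets[mirna] = set(inside) | set(outside)
        else:
            targets[mirna] = set(rng.choice(genes, size=min(b, n_gene), replace=False).tolist())
    return InteractionDB(targets=targets, terms=terms, term_categories=categories)


def simulate_qpcr(
    ground_truth: GroundTruth,
    assays: list[str],
    refs: list[str],
    fraction: str,
    n_per_group: int,
    cq_noise_sd: float = 0.2,
    sample_offset_sd: float = 0.5,
    base_cq: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cq tables mirroring the simulated abundances of one plasma fraction.

    Cq = base - log2(relative abundance) + per-sample RNA-input offset +
    N(0, cq_noise_sd); a planted fold-change f shows up as a -log2(f) group
    shift. The per-sample offset is shared by every assay and cancels exactly
    in delta-Cq, emulating variable RNA input per reaction.

    Returns the samples-by-assays Cq table and a group label per sample.
    """
    if not assays:
        raise ConfigError("empty assay list")
    if fraction not in ground_truth.baseline:
        raise ConfigError(f"no simulated fraction {fraction!r}")
    rng = np.random.default_rng(seed)
    share = ground_truth.baseline[fraction]
    mult = ground_truth.effect[fraction]
    all_assays = list(dict.fromkeys(list(assays) + list(refs)))
    missing = [a for a in all_assays if a not in share.index]
    if missing:
        raise ConfigError(f"assays not among simulated features: {missing}")

    samples = [f"V{i + 1:02d}" for i in range(2 * n_per_group)]
    groups = pd.Series([GROUPS[i // n_per_group] for i in range(2 * n_per_group)], index=samples, name="group")
    offsets = rng.normal(0.0, sample_offset_sd, len(samples))

    rows = {}
    for sample, offset in zip(samples, offsets):
        up = groups[sample] == "PTSD+"
        cqs = {}
        for assay in all_assays:
            abundance = share[assay] * (mult[assay] if up else 1.0)
            noise = rng.normal(0.0, cq_noise_sd) if cq_noise_sd > 0 else 0.0
            cqs[assay] = base_cq - math.log2(abundance) + offset + noise
        rows[sample] = cqs
    cq = pd.DataFrame.from_dict(rows, orient="index")[all_assays]
    cq.index.name = "sample"
    return cq, groups
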