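"""End-to-end orchestration: simulate -> filter -> DE -> qPCR -> enrichment.

``run_pipeline`` executes the full analysis on a seeded synthetic cohort (or
user-supplied count tables), writes every intermediate as plain text, and
returns a machine-readable summary whose counts are all reproducible from the
emitted files. All thresholds default to the study's stated values and every
applied threshold is logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .detection import composition_summary, detection_sets, filter_reliable
from .enrichment import enrich_terms, fes_background, fes_records_frame, get_targets
from .io import (
    ConfigError,
    CountMatrix,
    DataError,
    read_counts,
    write_counts,
    write_cq,
    write_fasta,
    write_gmt,
    write_interactions,
    write_json,
    write_samples,
)
from .normde import call_de, cpm, ev_partition, motif_scan, nb_exact_test, tmm_factors
from .normde import estimate_common_dispersion
from .qpcr import concordance, normalize_cq, select_reference_mirnas, welch_test
from .simulate import SimConfig, simulate_annotations, simulate_cohort, simulate_qpcr, simulate_sequences

log = logging.getLogger("cfmir")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run (defaults = study values)."""

    # detection filter
    min_reads: int = 5
    min_sample_share: float = 0.5
    # differential abundance calling
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    # qPCR reference selection
    ref_fc_max: float = 1.1
    ref_p_min: float = 0.05
    ref_cv_max: float = 0.05
    n_refs: int = 4
    # enrichment / FES
    enrich_p: float = 0.1
    enrich_min_overlap: int = 3
    fes_top_share: float = 0.05
    # motif scan
    motif_mode: str = "suffix"
    motif_window: int = 6
    motif_fraction: float = 0.25
    # qPCR validation cohort
    n_validation_per_group: int = 10
    qpcr_noise_sd: float = 0.2
    max_qpcr_assays: int = 16
    # synthetic annotation database
    n_annotation_genes: int = 2000
    n_annotation_terms: int = 30
    planted_fes: float = 5.0
    # inputs: either simulate (default) or load per-fraction TSVs
    simulation: SimConfig = field(default_factory=SimConfig)
    counts_paths: dict[str, str] | None = None
    samples_path: str | None = None
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        positive = {
            "min_reads": self.min_reads, "min_sample_share": self.min_sample_share,
            "p_cutoff": self.p_cutoff, "fc_cutoff": self.fc_cutoff,
            "ref_fc_max": self.ref_fc_max, "ref_p_min": self.ref_p_min,
            "ref_cv_max": self.ref_cv_max, "n_refs": self.n_refs,
            "enrich_p": self.enrich_p, "enrich_min_overlap": self.enrich_min_overlap,
            "fes_top_share": self.fes_top_share,
        }
        for name, value in positive.items():
            if value <= 0 and name != "p_cutoff":
                raise ConfigError(f"{name} must be positive (got {value})")
        if self.p_cutoff < 0:
            raise ConfigError("p_cutoff must be >= 0")

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["de_spec"] = [dataclasses.asdict(e) for e in self.simulation.de_spec]
        return out


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 131 + k * 7919 + 17) % (2**31 - 1)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ConfigError, DataError, PipelineError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(name, str(exc)) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; return the RunSummary dict (also written as JSON).

    Deterministic for a fixed config and seed. Stages: cohort simulation or
    loading, reliable-detection filtering, detection-set Venn, RNA-type
    composition, per-fraction TMM + exact-test differential abundance, EV/EVD
    partition with 3'-motif scan, sequencing-guided reference selection, qPCR
    simulation + delta-Cq Welch validation, and target enrichment with
    background FES percentiles for the validated candidates.
    """
    config.validate()
    seed = config.seed
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("thresholds: filter >=%d reads in >%d%% samples; DE p<%g FC>%g; "
             "refs FC<%g p>%g CV<%g k=%d; enrich p<%g overlap>=%d; FES top %g",
             config.min_reads, round(config.min_sample_share * 100), config.p_cutoff,
             config.fc_cutoff, config.ref_fc_max, config.ref_p_min, config.ref_cv_max,
             config.n_refs, config.enrich_p, config.enrich_min_overlap, config.fes_top_share)

    # -- inputs -------------------------------------------------------------
    if config.counts_paths:
        if not config.samples_path:
            raise ConfigError("samples_path required when loading count tables")
        tables = {f: read_counts(p, config.samples_path) for f, p in config.counts_paths.items()}
        samples = pd.concat([cm.samples for cm in tables.values()]).drop_duplicates()
        ground_truth = None
    else:
        sim_cfg = dataclasses.replace(config.simulation, seed=_sub_seed(seed, 0))
        tables, samples, ground_truth = _stage("simulate")(simulate_cohort, sim_cfg)
    fractions = list(tables)

    if outdir:
        write_samples(samples, outdir / "samples.tsv")
        for frac, cm in tables.items():
            write_counts(cm, outdir / f"counts_{frac}.tsv")
        if ground_truth is not None:
            write_json(ground_truth.to_dict(), outdir / "ground_truth.json")

    # -- detection + composition -------------------------------------------
    filtered = {
        frac: _stage("filter")(filter_reliable, cm, config.min_reads, config.min_sample_share)
        for frac, cm in tables.items()
    }
    mirna_filtered = {
        frac: cm.subset_features(cm.features[cm.feature_types == "miRNA"])
        for frac, cm in filtered.items()
    }
    venn = None
    if len(fractions) >= 2:
        venn = _stage("venn")(detection_sets, mirna_filtered)
    composition = _stage("composition")(composition_summary, tables)

    # -- per-fraction differential abundance --------------------------------
    de_results: dict[str, pd.DataFrame] = {}
    called_up: dict[str, set] = {}
    called_down: dict[str, set] = {}
    factors_by_fraction: dict[str, pd.Series] = {}
    dispersion_by_fraction: dict[str, float] = {}
    for frac, cm in filtered.items():
        groups = cm.groups()
        factors = _stage("tmm")(tmm_factors, cm)
        disp = _stage("dispersion")(estimate_common_dispersion, cm, groups, factors)
        res = _stage("exact_test")(nb_exact_test, cm, groups, factors, disp,
                                   numerator="PTSD+", denominator="PTSD-")
        res, up, down = _stage("call_de")(call_de, res, config.p_cutoff, config.fc_cutoff)
        de_results[frac] = res
        called_up[frac], called_down[frac] = up, down
        factors_by_fraction[frac] = factors
        dispersion_by_fraction[frac] = disp
        log.info("fraction %s: %d features detected, %d called (%d up / %d down), phi=%.4g",
                 frac, len(cm.features), len(up) + len(down), len(up), len(down), disp)
        if outdir:
            res.to_csv(outdir / f"de_{frac}.tsv", sep="\t", index_label="feature")
            factors.to_frame().to_csv(outdir / f"tmm_{frac}.tsv", sep="\t", index_label="sample")

    # -- EV/EVD partition + motif scan --------------------------------------
    ev_summary = None
    if "EV" in mirna_filtered and "EVD" in mirna_filtered:
        enriched, underrep, ev_res = _stage("ev_partition")(
            ev_partition, mirna_filtered["EV"], mirna_filtered["EVD"],
            config.p_cutoff, config.fc_cutoff)
        n_mirna_total = config.simulation.n_mirna if ground_truth is not None else len(ev_res)
        seqs = _stage("sequences")(
            simulate_sequences, n_mirna_total, config.motif_fraction, _sub_seed(seed, 1))
        scan_enriched = _stage("motif_scan")(motif_scan, seqs, sorted(enriched),
                                             mode=config.motif_mode, window_nt=config.motif_window)
        scan_under = _stage("motif_scan")(motif_scan, seqs, sorted(underrep),
                                          mode=config.motif_mode, window_nt=config.motif_window)
        ev_summary = {
            "n_ev_enriched": len(enriched),
            "n_ev_underrepresented": len(underrep),
            "motif_hits_enriched": scan_enriched.n_hits,
            "motif_hits_underrepresented": scan_under.n_hits,
        }
        if outdir:
            ev_res.to_csv(outdir / "ev_partition.tsv", sep="\t", index_label="feature")
            write_fasta(seqs, outdir / "mirna_sequences.fasta")
            if len(scan_enriched.per_feature):
                scan_enriched.per_feature.to_csv(outdir / "motif_ev_enriched.tsv", sep="\t")
            if len(scan_under.per_feature):
                scan_under.per_feature.to_csv(outdir / "motif_ev_underrepresented.tsv", sep="\t")

    # -- qPCR reference selection + validation ------------------------------
    mirna_de = {f: de_results[f].loc[de_results[f].index.isin(mirna_filtered[f].features)]
                for f in fractions}
    norm_counts = {
        f: cpm(filtered[f], factors_by_fraction[f]).loc[mirna_filtered[f].features]
        for f in fractions
    }
    group_labels = {f: filtered[f].groups() for f in fractions}
    refs = _stage("select_refs")(select_reference_mirnas, mirna_de, norm_counts, group_labels,
                                 config.ref_fc_max, config.ref_p_min, config.ref_cv_max,
                                 config.n_refs)
    if outdir:
        write_json(refs.to_dict(), outdir / "reference_set.json")
        refs.diagnostics.to_csv(outdir / "reference_diagnostics.tsv", sep="\t", index_label="feature")

    validated: dict[str, list[str]] = {}
    qpcr_summary: dict[str, dict] = {}
    if ground_truth is not None and refs.members:
        for i, frac in enumerate(fractions):
            called = sorted(called_up[frac] | called_down[frac])
            assays = [f for f in called if f in set(mirna_filtered[frac].features)]
            assays = sorted(assays, key=lambda f: de_results[frac].loc[f, "p_value"])
            assays = assays[: config.max_qpcr_assays]
            if not assays:
                validated[frac] = []
                continue
            cq, cq_groups = _stage("simulate_qpcr")(
                simulate_qpcr, ground_truth, assays, refs.members, frac,
                config.n_validation_per_group, config.qpcr_noise_sd,
                seed=_sub_seed(seed, 10 + i))
            norm = _stage("normalize_cq")(normalize_cq, cq, refs)
            welch = _stage("welch")(welch_test, norm, cq_groups)
            welch = welch.loc[[a for a in assays if a in welch.index]]
            report, agreement = _stage("concordance")(concordance, de_results[frac], welch,
                                                      config.p_cutoff)
            confirmed = report.index[
                report["direction_agrees"]
                & (welch.loc[report.index, "p_value"] < config.p_cutoff)
            ]
            validated[frac] = sorted(confirmed)
            qpcr_summary[frac] = {
                "n_assays": len(assays),
                "n_confirmed": len(validated[frac]),
                "direction_concordance": agreement,
            }
            if outdir:
                write_cq(cq, outdir / f"cq_{frac}.csv")
                welch.to_csv(outdir / f"qpcr_{frac}.tsv", sep="\t", index_label="assay")
                report.to_csv(outdir / f"concordance_{frac}.tsv", sep="\t", index_label="feature")

    # -- target enrichment + FES for validated candidates -------------------
    fes_summary = []
    enrichment_written = False
    validated_all = sorted({m for feats in validated.values() for m in feats})
    if ground_truth is not None and validated_all:
        planted_pairs = []
        planted_features = sorted({e.feature for e in ground_truth.true_de})
        for j, feat in enumerate(planted_features):
            planted_pairs.append((feat, f"TERM{j + 1:04d}", config.planted_fes))
        db = _stage("annotations")(
            simulate_annotations, config.simulation.n_mirna, config.n_annotation_genes,
            config.n_annotation_terms, planted_pairs, _sub_seed(seed, 2))
        if outdir:
            write_interactions(db.targets, outdir / "interactions.tsv")
            write_gmt(db.terms, outdir / "terms.gmt", db.term_categories)
        altered = sorted(set().union(*called_up.values(), *called_down.values()))
        planted_term = dict((f, t) for f, t, _ in planted_pairs)
        for mirna in validated_all:
            if mirna not in db.targets:
                continue
            targets = get_targets(mirna, db)
            enr = _stage("enrich")(enrich_terms, targets, db,
                                   config.enrich_p, config.enrich_min_overlap)
            selected_terms = list(enr.index[enr["selected"]])
            terms_to_score = selected_terms or ([planted_term[mirna]] if mirna in planted_term else [])
            records = _stage("fes")(fes_background, mirna, terms_to_score, db,
                                    exclude=[m for m in altered if m != mirna],
                                    top_share=config.fes_top_share) if terms_to_score else []
            fes_summary.append({
                "mirna": mirna,
                "n_targets": len(targets),
                "n_selected_terms": len(selected_terms),
                "planted_term": planted_term.get(mirna),
                "planted_term_selected": planted_term.get(mirna) in selected_terms,
                "top5_terms": [r.term for r in records if r.top5],
            })
            if outdir:
                enr.to_csv(outdir / f"enrichment_{mirna}.tsv", sep="\t", index_label="term")
                fes_records_frame(records).to_csv(outdir / f"fes_{mirna}.tsv", sep="\t", index=False)
                enrichment_written = True

    summary = {
        "version": __version__,
        "seed": seed,
        "config": config.echo(),
        "fractions": {
            frac: {
                "n_samples": int(tables[frac].counts.shape[1]),
                "n_features_input": int(tables[frac].counts.shape[0]),
                "n_detected": int(len(filtered[frac].features)),
                "n_detected_mirna": int(len(mirna_filtered[frac].features)),
                "n_called": len(called_up[frac]) + len(called_down[frac]),
                "n_called_up": len(called_up[frac]),
                "n_called_down": len(called_down[frac]),
                "called_up": sorted(called_up[frac]),
                "called_down": sorted(called_down[frac]),
                "dispersion": dispersion_by_fraction[frac],
            }
            for frac in fractions
        },
        "venn": venn.to_dict() if venn else None,
        "composition_means": composition.fraction_means.round(6).to_dict(),
        "ev_partition": ev_summary,
        "reference_mirnas": refs.members,
        "qpcr": qpcr_summary,
        "validated_candidates": validated,
        "validated_candidates_all": validated_all,
        "fes": fes_summary,
    }
    if outdir:
        write_json(summary, outdir / "run_summary.json")
        composition.per_sample.to_csv(outdir / "composition_per_sample.tsv", sep="\t",
                                      index_label="sample")
        composition.comparisons.to_csv(outdir / "composition_tests.tsv", sep="\t", index=False)
        if venn:
            write_json(venn.to_dict(), outdir / "venn.json")
    _ = enrichment_written
    return summary
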