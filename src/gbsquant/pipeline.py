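"""End-to-end driver: simulate a study, run every processing stage, and
evaluate the resulting abundance estimates against the design truth.

The driver exists so tests, the CLI, and the acceptance script share one
code path.  All tunables live in :class:`SimulationConfig`; the defaults
emulate the real study's shape (6 strains, one hybrid, 32-fold yield
spread, ~50 % PCR duplicates, 25 mock + 5 calibration + 6 monoclonal
samples) at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cluster_filtering as cf
from . import evaluation as ev
from . import meta_reference as mr
from . import preprocessing as pp
from . import quantification as qt
from . import read_mapping as rm
from . import synthetic_data as sd

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_strains: int = 6
    genome_length: int = 100_000
    divergences: tuple[float, ...] | None = None
    hybrid: bool = True
    site_spacing: tuple[int, int] = (200, 800)
    yield_factors: tuple[float, ...] | None = None
    duplicate_rate: float = 0.5
    error_rate: float = 0.001
    reads_monoclonal: int = 12_000
    reads_calibration: int = 6_000
    reads_mock: int = 4_000
    mock_sizes: tuple[int, ...] | None = None  # None = the study's 18/3/3/1 design
    # processing thresholds
    min_overlap: int = 20
    max_mismatch_frac: float = 0.10
    min_unique_size: int = 5
    cluster_identity: float = 0.95
    score_min: float = 0.8
    max_hits: int = 50
    prefilter_k: int | None = 16
    min_target: float = 8
    ratio_max: float = 1 / 15
    # synthetic depths run ~20x below the real study, so the sample-exclusion
    # threshold scales down with them (the operation default stays 3000)
    min_reads: float = 1000
    min_target_rate: float | None = None
    # light microscopy
    lm_n_valves: int = 200
    confusion: pd.DataFrame | None = None
    contaminant_classifier: Callable[[str], bool] | None = None
    exact_reads: bool = False

    def resolved_divergences(self) -> tuple[float, ...]:
        if self.divergences is not None:
            return tuple(self.divergences)
        base = (0.01, 0.02, 0.03, 0.04, 0.05, 0.015, 0.025, 0.035)
        if self.n_strains > len(base):
            raise ValueError("provide divergences explicitly for this many strains")
        return base[: self.n_strains]

    def resolved_yields(self, strain_ids: Sequence[str]) -> dict[str, float]:
        if self.yield_factors is not None:
            ys = self.yield_factors
        else:
            # geometric ladder spanning 32-fold for 6 strains
            ys = tuple(0.25 * 2**i for i in range(len(strain_ids)))
        return dict(zip(strain_ids, ys))

    def hybrid_spec(self) -> sd.HybridSpec | None:
        if not self.hybrid:
            return None
        n_seg = 9
        bps = tuple(
            round(self.genome_length * i / n_seg) for i in range(1, n_seg)
        )
        return sd.HybridSpec(parent_a=0, parent_b=1, breakpoints=bps, child=-1)


def default_lm_confusion(
    strain_ids: Sequence[str],
    hybrid_id: str | None,
    similar: Sequence[str] = (),
    mutual_leak: float = 0.001,
    into_hybrid_similar: float = 0.12,
    into_hybrid_other: float = 0.05,
    hybrid_back_leak: float = 0.001,
) -> pd.DataFrame:
    """Row-stochastic misidentification matrix for simulated expert counts.

    Confusion is concentrated among the look-alike group and directed at
    the hybrid: every strain leaks into the hybrid (its deformed valves
    attract wrong calls, strongly so for its look-alikes), while leaks
    between non-hybrid strains stay small and probabilistic.  Without a
    hybrid, the look-alikes are simply confused among themselves.
    """
    ids = list(strain_ids)
    m = pd.DataFrame(0.0, index=ids, columns=ids)
    similar = [s for s in similar if s in ids]
    for s in ids:
        row = dict.fromkeys(ids, 0.0)
        if hybrid_id is None:
            if s in similar:
                for t in similar:
                    if t != s:
                        row[t] += 0.10
        elif s == hybrid_id:
            for t in [t for t in similar if t != s][:2]:
                row[t] += hybrid_back_leak
        else:
            row[hybrid_id] += (
                into_hybrid_similar if s in similar else into_hybrid_other
            )
            if s in similar:
                for t in similar:
                    if t not in (s, hybrid_id):
                        row[t] += mutual_leak
        row[s] = 1.0 - sum(row.values())
        m.loc[s] = pd.Series(row)
    return m


@dataclass
class PipelineResult:
    config: SimulationConfig
    seed: int
    designs: list[sd.SampleDesign]
    panel: sd.StrainPanel
    fragments: dict[str, list[sd.Fragment]]
    barcode_map: dict[str, str]
    n_raw_reads: int
    n_unassigned: int
    sample_stats: pd.DataFrame  # per sample: reads, merged/joined/dup fractions
    reference_full: mr.MetaReference
    reference: mr.MetaReference  # after homologous-cluster removal
    mapping: rm.MappingResult
    homology_stats: list[cf.ClusterHomologyStats]
    filter_report: cf.FilterReport
    matrix: rm.CountMatrix  # post-filter, post-exclusion
    excluded_samples: list[tuple[str, float]]
    target_rates: dict[str, float]
    counts: pd.DataFrame  # sample × strain
    key: qt.CalibrationKey
    gbs: qt.AbundanceTable
    expected: qt.AbundanceTable
    lm: qt.AbundanceTable
    lm_counts: dict[str, dict[str, int]]
    sample_stats_gbs: pd.DataFrame
    sample_stats_lm: pd.DataFrame
    strain_stats_gbs: pd.DataFrame
    comparison: pd.DataFrame
    comparison_summary: dict
    detection_gbs: ev.DetectionReport
    detection_lm: ev.DetectionReport
    false_signal: tuple[pd.Series, float]

    def mock_sample_ids(self) -> list[str]:
        return list(self.gbs.sample_ids)


def run_pipeline(
    config: SimulationConfig | None = None, seed: int = 1
) -> PipelineResult:
    config = config or SimulationConfig()
    s_genome, s_design, s_bias, s_lm = (
        int(x) for x in np.random.SeedSequence(seed).generate_state(4)
    )

    # --- simulate -----------------------------------------------------------
    panel = sd.simulate_strain_genomes(
        config.n_strains,
        config.genome_length,
        config.resolved_divergences(),
        hybrid_spec=config.hybrid_spec(),
        seed=s_genome,
        site_spacing=config.site_spacing,
    )
    fragments = {g.strain_id: sd.digest_genome(g) for g in panel}
    if config.mock_sizes is not None:
        designs = sd.make_study_design(
            panel.strain_ids, seed=s_design, mock_sizes=config.mock_sizes
        )
    else:
        designs = sd.make_study_design(panel.strain_ids, seed=s_design)
    barcodes = sd.default_barcodes(len(designs))
    barcode_map = {d.sample_id: bc for d, bc in zip(designs, barcodes)}
    bias = sd.BiasModel(
        yield_factor=config.resolved_yields(panel.strain_ids),
        duplicate_rate=config.duplicate_rate,
        error_rate=config.error_rate,
        seed=s_bias,
    )
    reads_by_role = {
        "monoclonal": config.reads_monoclonal,
        "calibration": config.reads_calibration,
        "mock": config.reads_mock,
    }
    raw: list[tuple[str, str, str]] = []
    for d in designs:
        pairs = sd.generate_reads(
            fragments,
            d,
            bias,
            reads_per_cell=reads_by_role[d.role] / d.total_cells,
            barcode_map=barcode_map,
            exact=config.exact_reads,
        )
        raw.extend((p.read_id, p.barcode + p.umi + p.mate1, p.mate2) for p in pairs)

    # --- preprocess ---------------------------------------------------------
    demuxed, n_unassigned = pp.demultiplex(raw, barcode_map)
    role_of = {d.sample_id: d.role for d in designs}
    deduped: dict[str, list[pp.ProcessedRead]] = {}
    stat_rows = []
    for sample_id, pairs in demuxed.items():
        processed = pp.process_pairs(
            sample_id,
            pairs,
            min_overlap=config.min_overlap,
            max_mismatch_frac=config.max_mismatch_frac,
        )
        unique, dup_frac = pp.deduplicate(processed)
        deduped[sample_id] = unique
        stat_rows.append(
            (
                sample_id,
                role_of[sample_id],
                len(processed),
                pp.merged_fraction(processed),
                dup_frac,
            )
        )
    sample_stats = pd.DataFrame(
        stat_rows, columns=["sample_id", "role", "reads", "merged_fraction", "duplicate_fraction"]
    ).set_index("sample_id")

    # --- meta-reference -----------------------------------------------------
    mono_of = cf.monoclonal_sample_of(designs)
    per_strain: dict[str, list[mr.Cluster]] = {}
    for strain, sample_id in mono_of.items():
        uniques = pp.dereplicate(deduped[sample_id], config.min_unique_size)
        clusters = mr.cluster_sequences(
            uniques, identity=config.cluster_identity, strain_id=strain
        )
        clusters, _ = mr.contaminant_filter(clusters, config.contaminant_classifier)
        per_strain[strain] = clusters
    reference_full = mr.build_meta_reference(per_strain)

    # --- mapping ------------------------------------------------------------
    all_reads = [r for sample in deduped.values() for r in sample]
    mapping = rm.map_reads(
        all_reads,
        reference_full,
        score_min=config.score_min,
        max_hits=config.max_hits,
        prefilter_k=config.prefilter_k,
    )
    sample_ids = [d.sample_id for d in designs]
    cluster_ids = [c.cluster_id for c in reference_full.clusters]
    matrix_full = rm.build_count_matrix(mapping.events, cluster_ids, sample_ids)

    # --- homologous-cluster removal -----------------------------------------
    homology_stats = cf.compute_homology_stats(matrix_full, designs, reference_full)
    retained, filter_report = cf.filter_homologous(
        homology_stats, min_target=config.min_target, ratio_max=config.ratio_max
    )
    reference = reference_full.subset(retained)
    kept_events = [e for e in mapping.events if e.cluster_id in retained]
    matrix = rm.build_count_matrix(
        kept_events, [c.cluster_id for c in reference.clusters], sample_ids
    )
    target_rates = cf.target_mapping_rate(matrix, designs, reference)
    if config.min_target_rate is not None:
        cf.check_target_rates(target_rates, config.min_target_rate)

    # --- quantification -----------------------------------------------------
    matrix, excluded_samples = rm.exclude_low_read_samples(
        matrix, designs, min_reads=config.min_reads
    )
    counts = qt.strain_counts(matrix, reference)
    calib_ids = [d.sample_id for d in designs if d.role == "calibration"]
    key = qt.build_calibration_key(counts, calib_ids)
    mock_ids = [d.sample_id for d in designs if d.role == "mock"]
    gbs, _ = qt.estimate_abundances(counts, key, samples=mock_ids)

    dropped_strains = [
        s for s in panel.strain_ids if s not in reference.strain_ids
    ] + reference_full.excluded_strains
    expected_all, _ = qt.expected_abundances(designs, excluded_strains=dropped_strains)
    expected = qt.AbundanceTable(
        values=expected_all.values.loc[gbs.sample_ids], method="expected"
    )

    # --- light microscopy ---------------------------------------------------
    hybrid_id = next((g.strain_id for g in panel if g.is_hybrid), None)
    divs = config.resolved_divergences()
    similar = [
        panel.strain_ids[i] for i in np.argsort(divs)[:3]
    ]  # most look-alike = least diverged
    confusion = (
        config.confusion
        if config.confusion is not None
        else default_lm_confusion(panel.strain_ids, hybrid_id, similar=similar)
    )
    lm_counts = {}
    for i, d in enumerate(designs):
        if d.role != "mock":
            continue
        lm_counts[d.sample_id] = sd.simulate_lm_counts(
            d, confusion, n_valves=config.lm_n_valves, seed=s_lm + i
        )
    lm_all = qt.lm_abundances(lm_counts, excluded_strains=dropped_strains)
    lm = qt.AbundanceTable(
        values=lm_all.values.loc[[s for s in gbs.sample_ids]], method="LM"
    )

    # --- evaluation ---------------------------------------------------------
    sample_stats_gbs = ev.correlate(gbs, expected, unit="sample")
    sample_stats_lm = ev.correlate(lm, expected, unit="sample")
    strain_stats_gbs = ev.correlate(gbs, expected, unit="strain")
    comparison, summary = ev.compare_methods(sample_stats_gbs, sample_stats_lm)
    detection_gbs = ev.detect(gbs, expected)
    detection_lm = ev.detect(lm, expected)
    false_signal = ev.false_signal_rate(gbs, expected)

    return PipelineResult(
        config=config,
        seed=seed,
        designs=designs,
        panel=panel,
        fragments=fragments,
        barcode_map=barcode_map,
        n_raw_reads=len(raw),
        n_unassigned=n_unassigned,
        sample_stats=sample_stats,
        reference_full=reference_full,
        reference=reference,
        mapping=mapping,
        homology_stats=homology_stats,
        filter_report=filter_report,
        matrix=matrix,
        excluded_samples=excluded_samples,
        target_rates=target_rates,
        counts=counts,
        key=key,
        gbs=gbs,
        expected=expected,
        lm=lm,
        lm_counts=lm_counts,
        sample_stats_gbs=sample_stats_gbs,
        sample_stats_lm=sample_stats_lm,
        strain_stats_gbs=strain_stats_gbs,
        comparison=comparison,
        comparison_summary=summary,
        detection_gbs=detection_gbs,
        detection_lm=detection_lm,
        false_signal=false_signal,
    )


def accuracy_summary(result: PipelineResult) -> dict[str, float]:
    """Headline numbers for reports: mean per-sample r, mean absolute
    error, false-signal rate, method-comparison tallies."""
    stats = result.sample_stats_gbs
    computable = stats[stats["computable"]]
    obs, exp = ev._aligned(result.gbs, result.expected)
    mae = float((obs - exp).abs().to_numpy().mean())
    slopes = result.strain_stats_gbs.loc[
        result.strain_stats_gbs["computable"], "slope"
    ]
    return {
        "n_mock_samples": int(len(stats)),
        "mean_sample_r": float(computable["r"].mean()),
        "mean_abs_error": mae,
        "false_signal_mean": float(result.false_signal[1]),
        "key_spread": float(result.key.spread),
        "strain_slope_min": float(slopes.min()),
        "strain_slope_max": float(slopes.max()),
        "gbs_wins": int(result.comparison_summary.get("GBS", 0)),
        "lm_wins": int(result.comparison_summary.get("LM", 0)),
        "merged_fraction": float(
            (result.sample_stats["merged_fraction"] * result.sample_stats["reads"]).sum()
            / result.sample_stats["reads"].sum()
        ),
        "duplicate_fraction": float(
            (result.sample_stats["duplicate_fraction"] * result.sample_stats["reads"]).sum()
            / result.sample_stats["reads"].sum()
        ),
    }


def write_outputs(result: PipelineResult, outdir: str) -> None:
    """Write the standard file products of a run into ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)
    sd.write_designs(result.designs, join("designs.tsv"))
    sd.write_genomes(result.panel, join("genomes.fasta"))
    result.reference.to_fasta(join("meta_reference.fasta"))
    result.reference.cluster_table().to_csv(join("clusters.tsv"), sep="\t", index=False)
    result.matrix.to_long(result.reference).to_csv(join("cluster_counts.csv"), index=False)
    result.key.to_frame().to_csv(join("calibration_key.tsv"), sep="\t")
    qt.side_by_side(result.gbs, result.expected).to_csv(
        join("abundances_gbs.tsv"), sep="\t", index=False
    )
    qt.side_by_side(result.lm, result.expected).to_csv(
        join("abundances_lm.tsv"), sep="\t", index=False
    )
    result.sample_stats.to_csv(join("sample_stats.tsv"), sep="\t")
    result.filter_report.pairwise.to_csv(join("homology_pairwise.csv"))
    result.comparison.to_csv(join("method_comparison.tsv"), sep="\t")
    result.detection_gbs.per_strain.to_csv(join("detection_gbs.tsv"), sep="\t")
    result.detection_lm.per_strain.to_csv(join("detection_lm.tsv"), sep="\t")
    pd.Series(accuracy_summary(result)).to_csv(join("summary.tsv"), sep="\t", header=False)
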