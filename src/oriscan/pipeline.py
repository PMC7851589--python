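"""End-to-end orchestration: read → filter → reconstruct → map → regress → selection.

One config drives the full analysis; the run report echoes the effective
config (all defaults resolved), per-stage counts, and every summary table,
and each number in it is recomputable from the emitted TSVs.  All
randomness upstream lives in the simulator; the analysis itself is
deterministic, so identical inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import ancestral, blocks as blk, regression, selection, spatial
from .ancestral import Phylogeny
from .blocks import AlignedBlock, AnnotationTable, GeneSegment
from .replicon import Replicon, replicon_from_config
from .spatial import WINDOW_WIDTHS

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Resolved knobs of the analysis stages (filters, windows, outlier rule)."""

    max_gap_fraction: float = 0.2
    min_segment_length: int = 100
    excluded_blocks: Tuple[str, ...] = ()  # e.g. blocks failing a topology screen
    outlier_mode: str = "tukey"
    window: int = 10_000
    window_widths: Tuple[int, ...] = WINDOW_WIDTHS
    response: str = "indicator"  # logistic response column
    position_anchor: str = "parent"  # map events by parent or child position
    pooled_kappa: bool = True  # fit one ts/tv ratio across segments
    permutation_step: int = 10_000
    permutation_max_shift: int = 100_000


@dataclass
class AnalysisResult:
    """Everything the substitution stage produces for one replicon."""

    replicon: Replicon
    tree: Phylogeny
    segments: List[GeneSegment]
    events: List[ancestral.SubstitutionEvent]
    site_table: pd.DataFrame
    windows: pd.DataFrame
    logistic: regression.RegressionResult
    window_fits: List[regression.RegressionResult]
    counts: Dict[str, int]
    kappa: float
    position_reconstructions: Dict[str, ancestral.PositionReconstruction]


def _pooled_kappa(segments: Sequence[GeneSegment], tree: Phylogeny, max_cols: int = 20_000) -> float:
    """One transition/transversion ratio fitted on (a sample of) all segments."""
    seqs = {t: [] for t in tree.taxa}
    total = 0
    for seg in segments:
        for t in tree.taxa:
            seqs[t].append(seg.seqs[t])
        total += seg.length
        if total >= max_cols:
            break
    joined = {t: "".join(parts) for t, parts in seqs.items()}
    if not total:
        return 4.0
    codes = ancestral.encode_alignment(joined)
    pi = ancestral.empirical_base_frequencies(joined)
    return ancestral.fit_kappa(codes, tree, pi)


def substitution_analysis(
    blocks: Sequence[AlignedBlock],
    annotations: AnnotationTable,
    tree: Phylogeny,
    replicon: Replicon,
    config: Optional[AnalysisConfig] = None,
    exclude_taxon: Optional[str] = None,
) -> AnalysisResult:
    """Run the substitution half of the pipeline on one replicon."""
    cfg = config or AnalysisConfig()
    if exclude_taxon is not None:
        tree = tree.prune_taxon(exclude_taxon)
    counts = {"blocks_read": len(blocks)}

    universal = blk.select_universal_blocks(blocks, tree.taxa)
    universal = [b for b in universal if b.id not in set(cfg.excluded_blocks)]
    counts["blocks_kept"] = len(universal)

    prepared: List[Tuple[AlignedBlock, List[GeneSegment]]] = []
    removed_columns = 0
    for b in universal:
        trimmed = blk.gap_fraction_trim(b, cfg.max_gap_fraction)
        removed_columns += b.n_columns - trimmed.n_columns
        segs = blk.split_into_segments(
            trimmed, annotations, min_len=cfg.min_segment_length
        )
        if segs:
            prepared.append((trimmed, segs))
    segments = [s for _, segs in prepared for s in segs]
    counts["gap_trimmed_columns"] = removed_columns
    counts["segments"] = len(segments)
    counts["coding_sites"] = int(sum(s.length for s in segments))

    kappa = _pooled_kappa(segments, tree) if (cfg.pooled_kappa and segments) else None

    events: List[ancestral.SubstitutionEvent] = []
    site_positions: Dict[str, np.ndarray] = {}
    pos_recs: Dict[str, ancestral.PositionReconstruction] = {}
    for b, segs in prepared:
        labels = ancestral.leaf_block_labels(b)
        labels = {t: labels[t] for t in tree.taxa}
        pos_rec = ancestral.reconstruct_positions(labels, tree, block_id=b.id)
        pos_recs[b.id] = pos_rec
        anchor_node = tree.root
        for seg in segs:
            states = ancestral.reconstruct_nucleotides(seg, tree, kappa=kappa)
            seg_events = ancestral.extract_substitutions(states, tree, pos_rec, seg)
            if cfg.position_anchor == "child":
                for e in seg_events:
                    e.parent_position, e.child_position = e.child_position, e.parent_position
            events.extend(seg_events)
            site_positions[seg.id] = seg.position_maps[pos_rec.donors[anchor_node]]
    counts["events"] = len(events)

    site_table = spatial.build_site_table(events, segments, replicon, site_positions)
    windows = spatial.window_aggregate(site_table, cfg.window)
    mask = regression._window_outlier_site_mask(site_table, cfg.window)
    logistic = regression.fit_logistic(
        site_table, response=cfg.response, outlier_mask=mask,
        replicon=replicon.name, excluded_taxon=exclude_taxon,
    )
    window_fits = regression.fit_all_window_widths(site_table, cfg.window_widths)
    return AnalysisResult(
        replicon=replicon,
        tree=tree,
        segments=segments,
        events=events,
        site_table=site_table,
        windows=windows,
        logistic=logistic,
        window_fits=window_fits,
        counts=counts,
        kappa=float(kappa) if kappa else float("nan"),
        position_reconstructions=pos_recs,
    )


def selection_analysis(
    result: AnalysisResult, config: Optional[AnalysisConfig] = None
) -> Dict[str, object]:
    """Per-segment dN/dS/ω with outlier handling, genome averages, regressions."""
    cfg = config or AnalysisConfig()
    records = []
    for seg in result.segments:
        codon_seg = blk.trim_to_codons(seg)
        if codon_seg is None:
            continue
        records.append(selection.compute_dn_ds(codon_seg, replicon=result.replicon))
    selection.omega_outlier_filter(records, mode=cfg.outlier_mode)
    ds_bar, dn_bar, omega_bar = selection.weighted_genome_average(records)
    fits = selection.fit_selection_regressions(records, cfg.window_widths)
    return {
        "records": records,
        "ds_bar": ds_bar,
        "dn_bar": dn_bar,
        "omega_bar": omega_bar,
        "regressions": fits,
    }


def jackknife_analysis(
    blocks: Sequence[AlignedBlock],
    annotations: AnnotationTable,
    tree: Phylogeny,
    replicon: Replicon,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Taxon-removal sensitivity: rerun the substitution stage without each leaf."""
    cfg = config or AnalysisConfig()

    def rerun(excluded: Optional[str]) -> regression.RegressionResult:
        res = substitution_analysis(
            blocks, annotations, tree, replicon, cfg, exclude_taxon=excluded
        )
        return res.logistic

    return regression.taxon_jackknife(tree.taxa, rerun, tree=tree)


@dataclass
class RunReport:
    """Machine-readable report of one full run."""

    config: Dict[str, object]
    counts: Dict[str, int]
    mean_substitutions_per_bp: float
    logistic: Dict[str, object]
    window_regressions: List[Dict[str, object]]
    selection_summary: Dict[str, object]
    selection_regressions: List[Dict[str, object]]
    permutation: Optional[List[Dict[str, object]]] = None
    jackknife: Optional[List[Dict[str, object]]] = None
    warnings: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return str(obj)


def _result_dict(r: Optional[regression.RegressionResult]) -> Dict[str, object]:
    if r is None:
        return {}
    return {
        "model": r.model,
        "coefficient": r.coefficient,
        "intercept": r.intercept,
        "se": r.se,
        "p_value": r.p_value,
        "n": r.n,
        "r_squared": r.r_squared,
        "window": r.window,
        "flag": r.flag,
        "metadata": {k: _jsonable(v) if isinstance(v, (np.generic, np.ndarray)) else v
                     for k, v in r.metadata.items()},
    }


def run_full_analysis(
    blocks: Sequence[AlignedBlock],
    annotations: AnnotationTable,
    tree: Phylogeny,
    replicon: Replicon,
    config: Optional[AnalysisConfig] = None,
    outdir: Optional[Path] = None,
    with_permutation: bool = True,
    with_jackknife: bool = False,
) -> RunReport:
    """All stages in order; optional TSV emission; returns the run report."""
    cfg = config or AnalysisConfig()
    res = substitution_analysis(blocks, annotations, tree, replicon, cfg)
    sel = selection_analysis(res, cfg)
    perm = None
    if with_permutation:
        perm = regression.origin_shift_permutation(
            res.site_table, replicon,
            step=cfg.permutation_step, max_shift=cfg.permutation_max_shift,
            outlier_window=cfg.window,
        )
    jk = None
    if with_jackknife:
        jk = jackknife_analysis(blocks, annotations, tree, replicon, cfg)

    report = RunReport(
        config={"replicon": {"name": replicon.name, "length": replicon.length,
                             "topology": replicon.topology.value,
                             "origin": replicon.origin, "terminus": replicon.terminus,
                             "terminus_rule": replicon.terminus_rule.value},
                "analysis": asdict(cfg)},
        counts=res.counts,
        mean_substitutions_per_bp=spatial.mean_substitutions_per_bp(
            res.site_table, res.windows, cfg.window
        ),
        logistic=_result_dict(res.logistic),
        window_regressions=[_result_dict(r) for r in res.window_fits],
        selection_summary={
            "dS_bar": sel["ds_bar"], "dN_bar": sel["dn_bar"], "omega_bar": sel["omega_bar"],
            "n_records": len(sel["records"]),
            "n_outliers": sum(r.outlier for r in sel["records"]),
        },
        selection_regressions=[_result_dict(r) for r in sel["regressions"]],
        permutation=None if perm is None else perm.to_dict(orient="records"),
        jackknife=None if jk is None else jk.to_dict(orient="records"),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spatial.site_table_to_tsv(res.site_table, outdir / "site_table.tsv")
        spatial.windows_to_tsv(res.windows, outdir / "windows.tsv")
        pd.DataFrame(ancestral.events_to_rows(res.events)).to_csv(
            outdir / "events.tsv", sep="\t", index=False
        )
        selection.records_to_frame(sel["records"]).to_csv(
            outdir / "selection.tsv", sep="\t", index=False
        )
        regression.results_to_frame(
            [res.logistic] + res.window_fits + sel["regressions"]
        ).to_csv(outdir / "regressions.tsv", sep="\t", index=False)
        if perm is not None:
            perm.to_csv(outdir / "permutation.tsv", sep="\t", index=False)
        if jk is not None:
            jk.to_csv(outdir / "jackknife.tsv", sep="\t", index=False)
        (outdir / "run_report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# config loading


def load_run_config(path) -> Dict[str, object]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_inputs(cfg: Dict[str, object]):
    """Read (blocks, annotations, tree, replicon) per the config's input section."""
    inputs = cfg["inputs"]
    rep = replicon_from_config(cfg["replicon"])
    blocks = blk.read_blocks(inputs["blocks"], fmt=inputs.get("format", "xmfa"))
    ann_fmt = inputs.get("annotations_format", "tsv")
    if ann_fmt == "tsv":
        annotations = AnnotationTable.read_tsv(inputs["annotations"])
    else:
        annotations = AnnotationTable.read_gff3(inputs["annotations"])
    tree = Phylogeny.from_file(inputs["tree"])
    return blocks, annotations, tree, rep


def analysis_config_from(cfg: Dict[str, object]) -> AnalysisConfig:
    section = dict(cfg.get("analysis", {}))
    if "excluded_blocks" in section:
        section["excluded_blocks"] = tuple(section["excluded_blocks"])
    if "window_widths" in section:
        section["window_widths"] = tuple(section["window_widths"])
    return AnalysisConfig(**section)
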