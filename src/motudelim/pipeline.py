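"""Run every requested delimitation method on one dataset and score it.

The pipeline reproduces the method-comparison layout of a barcode
delimitation study: per-method MOTU partitions, a summary table of
N_match / N_MOTU / match ratio against the reference morphospecies, a
distance summary with histogram, per-species agreement classes, and a
monophyly report.  External partitions (e.g. BIN assignments computed by
a database service) are scored exactly like internal methods.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .cluster import (
    AbgdConfig,
    TcsConfig,
    abgd_scan,
    abgd_select_best,
    tcs_partition,
    threshold_cluster,
)
from .compare import MatchReport, classes_table, compare_partitions, report_table
from .distances import distance_summary, pairwise_distances, summary_table
from .io import (
    Alignment,
    Partition,
    PhyloTree,
    SpecimenTable,
    ValidationError,
    read_alignment,
    read_partition_table,
    read_specimen_table,
    read_tree,
    validate_against_alignment,
    write_partition_table,
)
from .treedelim import (
    McmcConfig,
    build_nj,
    midpoint_root,
    monophyly_report,
    mptp_ml,
    ptp_mcmc_support,
    ptp_ml,
)

ALL_METHODS = ("threshold", "abgd", "tcs", "ptp", "bptp", "mptp")
TREE_METHODS = {"ptp", "bptp", "mptp"}


@dataclass
class PipelineConfig:
    alignment: Optional[str] = None
    labels: Optional[str] = None
    tree: Optional[str] = None
    external_partitions: Dict[str, str] = field(default_factory=dict)
    methods: List[str] = field(default_factory=lambda: list(ALL_METHODS))
    out_dir: str = "delimit_out"
    seed: int = 123
    threshold: float = 0.03
    threshold_model: str = "k80"
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    mcmc: Optional[McmcConfig] = None
    distance_threshold: float = 0.03
    mptp_minbr: Optional[float] = None  # None = auto (1/alignment length)

    def __post_init__(self) -> None:
        known = set(ALL_METHODS) | {"external"}
        bad = [m for m in self.methods if m not in known]
        if bad or not self.methods:
            raise ValidationError(f"unknown or empty methods: {bad}")


def run_pipeline(
    cfg: PipelineConfig,
    alignment: Optional[Alignment] = None,
    labels: Optional[SpecimenTable] = None,
    tree: Optional[PhyloTree] = None,
    external: Optional[Dict[str, Partition]] = None,
) -> Dict[str, object]:
    """Execute the requested methods; write the report bundle to out_dir.

    Inputs may be passed in memory (simulation studies) or as paths in the
    config.  Any stage failure removes partial outputs and re-raises with
    the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        if alignment is None:
            alignment = read_alignment(cfg.alignment)
        if labels is None:
            labels = read_specimen_table(cfg.labels)
        validate_against_alignment(labels, alignment)
        if tree is None and cfg.tree:
            tree = read_tree(cfg.tree)
        external = dict(external or {})
        for name, path in cfg.external_partitions.items():
            external[name] = read_partition_table(path, method=name)

        stage = "distances"
        dm_thr = pairwise_distances(alignment, cfg.threshold_model)
        dm_abgd = (
            dm_thr
            if cfg.abgd.model == cfg.threshold_model
            else pairwise_distances(alignment, cfg.abgd.model)
        )
        summary = distance_summary(dm_thr, labels, t=cfg.distance_threshold)
        (out / "distance_summary.tsv").write_text(summary_table(summary))
        hist_lines = ["bin_low\tbin_high\tinfraspecific\tinterspecific"]
        n_bins = max(
            (len(v) for v in summary.histogram.values()), default=0
        )
        for b in range(n_bins):
            lo, hi = b * summary.bin_width, (b + 1) * summary.bin_width
            infra = summary.histogram.get("infraspecific")
            inter = summary.histogram.get("interspecific")
            hist_lines.append(
                f"{lo:.2f}\t{hi:.2f}\t"
                f"{int(infra[b]) if infra is not None and b < len(infra) else 0}\t"
                f"{int(inter[b]) if inter is not None and b < len(inter) else 0}"
            )
        (out / "distance_histogram.tsv").write_text("\n".join(hist_lines) + "\n")

        needs_tree = any(m in TREE_METHODS for m in cfg.methods)
        if needs_tree and tree is None:
            stage = "nj-fallback"
            import warnings

            warnings.warn(
                "no input tree supplied; falling back to an internal "
                "neighbor-joining tree — tree-based results will not match "
                "a model-based ML tree"
            )
            tree = build_nj(dm_thr)
        if tree is not None and not tree.rooted:
            tree = midpoint_root(tree)

        partitions: Dict[str, Partition] = {}
        provenance: Dict[str, dict] = {}
        for method in cfg.methods:
            stage = method
            if method == "threshold":
                p = threshold_cluster(dm_thr, cfg.threshold)
                prov = {"model": cfg.threshold_model, "threshold": cfg.threshold}
            elif method == "abgd":
                scan = abgd_scan(dm_abgd, cfg.abgd)
                p = abgd_select_best(scan)
                prov = {
                    "model": cfg.abgd.model,
                    "priors": [round(float(x), 6) for x in cfg.abgd.priors()],
                    "counts": [part.n_groups for _, part in scan],
                    "chosen": p.method,
                }
            elif method == "tcs":
                tcs_cfg = TcsConfig(alignment_length=alignment.length)
                p = tcs_partition(alignment, tcs_cfg)
                prov = {
                    "connection_probability": tcs_cfg.connection_probability,
                    "partition_tag": p.method,
                }
            elif method == "ptp":
                d = ptp_ml(tree)
                p = Partition(groups=dict(d.partition.groups), method="ptp")
                prov = {"log_likelihood": d.log_likelihood}
            elif method == "bptp":
                mc = cfg.mcmc or McmcConfig(seed=cfg.seed)
                d = ptp_mcmc_support(tree, mc)
                p = Partition(groups=dict(d.partition.groups), method="bptp")
                prov = {
                    "log_likelihood": d.log_likelihood,
                    "generations": mc.generations,
                    "thinning": mc.thinning,
                    "burn_in": mc.burn_in,
                    "seed": mc.seed,
                    "support": d.support,
                }
            elif method == "mptp":
                minbr = (
                    cfg.mptp_minbr
                    if cfg.mptp_minbr is not None
                    else 1.0 / alignment.length  # auto: one substitution on the locus
                )
                d = mptp_ml(tree, minbr=minbr)
                p = Partition(groups=dict(d.partition.groups), method="mptp")
                prov = {"log_likelihood": d.log_likelihood, "minbr": minbr}
            elif method == "external":
                continue
            prov.setdefault("tag", p.method)
            partitions[method] = Partition(groups=dict(p.groups), method=method)
            provenance[method] = prov
        for name, p in external.items():
            partitions[name] = Partition(groups=dict(p.groups), method=name)
            provenance[name] = {"source": "external partition file"}

        stage = "compare"
        morph = labels.to_partition()
        reports: List[MatchReport] = []
        for name in partitions:
            write_partition_table(partitions[name], out / f"partition_{name}.tsv")
            reports.append(compare_partitions(partitions[name], morph))
        (out / "summary.tsv").write_text(report_table(reports))
        (out / "agreement_classes.tsv").write_text(classes_table(reports))

        stage = "monophyly"
        mono = monophyly_report(tree, labels) if tree is not None else {}
        if mono:
            lines = ["species\tstatus"]
            lines += [f"{sp}\t{mono[sp]}" for sp in sorted(mono)]
            (out / "monophyly.tsv").write_text("\n".join(lines) + "\n")

        stage = "provenance"
        (out / "provenance.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "seed": cfg.seed,
                    "methods": list(partitions),
                    "parameters": provenance,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    except Exception as err:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "partitions": partitions,
        "reports": {r.method: r for r in reports},
        "summary": summary,
        "monophyly": mono,
        "tree": tree,
    }
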