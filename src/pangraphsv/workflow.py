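"""End-to-end desk-scale pipeline orchestration.

Glue that runs the whole method on one synthetic population: simulate,
emit and re-read the graph and paths through their file formats, partition
the graph, call and classify SVs, convert deletions to virtual SNPs,
genotype a bull cohort, scan with the weighted mixed model and group the
significant markers into QTL regions.  Returns every intermediate product
so callers can audit each stage against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
import pandas as pd

from . import assoc, graph_io, graph_partition, sv_catalog, virtual_snp
from . import synthetic_data as sd


@dataclass
class PipelineResult:
    truth: sd.GroundTruth
    partition: graph_partition.PartitionSummary
    records: list
    nrs_nodes: set[str]
    nrui_nodes: set[str]
    virtual_snps: list
    causal_sv: str
    null_model: assoc.NullModel
    scan: list
    threshold_neglog10: float
    qtl_regions: list
    marker_positions: dict[str, int] = field(default_factory=dict)

    def top_sv_marker(self) -> str:
        sv_hits = [r for r in self.scan if r.marker_id.startswith("sv_")]
        return min(sv_hits, key=lambda r: r.p_value).marker_id


def run_desk_pipeline(seed: int, n_bulls_per_family: int = 10,
                      n_families: int = 100, causal_var_frac: float = 0.05,
                      work_dir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline on the desk preset under one seed.

    The assembly panel (graph + paths) provides the SV catalog; a
    half-sib bull cohort provides SNPs for the GRM and diploid dosages of
    the called, virtual-SNP-convertible deletions, one of which is made
    causal for the simulated DYD trait.  All file formats are exercised:
    the graph and paths are written to disk and read back before calling.
    """
    cfg = sd.desk_preset(seed=seed, causal_var_frac=causal_var_frac)
    truth = sd.simulate_population(cfg)
    graph0, paths0 = sd.emit_graph_and_paths(truth)

    def _body(tmp: Path) -> PipelineResult:
        graph_io.write_gfa(graph0, tmp / "graph.gfa")
        graph_io.write_path_bed(paths0, tmp / "paths.bed")
        graph = graph_io.read_gfa(tmp / "graph.gfa")
        paths = graph_io.read_path_bed(tmp / "paths.bed", graph)

        occ = graph_partition.compute_occupancy(graph, paths)
        part = graph_partition.partition_core_flexible(occ, graph)
        nrs = graph_partition.extract_nrs(graph, occ, min_len=cfg.min_sv_len)

        records = sv_catalog.call_svs(graph, paths,
                                      min_sv_len=cfg.min_sv_len)
        nrui = sv_catalog.extract_nrui(records, graph,
                                       min_len=cfg.min_sv_len)
        graph_io.write_vcf(records, {cfg.chromosome: truth.reference},
                           tmp / "svs.vcf")

        # deletions -> virtual SNPs; only forward-convertible ones join
        # the genotyping panel
        vsnps = []
        for rec in records:
            if rec.sv_type != "DEL" or rec.allelicity != "biallelic":
                continue
            v = virtual_snp.convert_deletion(
                truth.reference, virtual_snp.from_half_open(rec.start, rec.end),
                chromosome=rec.chromosome, sv_id=rec.sv_id)
            vsnps.append(v)
        panel_ids = [v.sv_id for v in vsnps if v.forward_convertible]

        # bull cohort: half-sib SNPs for the GRM, HWE deletion dosages
        rng = np.random.default_rng(seed + 101)
        snp = sd.simulate_halfsib_genotypes(n_families, n_bulls_per_family,
                                            cfg.n_snps, rng)
        by_start = {(r.start, r.end): r for r in records}
        planted_by_pos = {(sv.start, sv.end): sv for sv in truth.svs}
        sv_cols, positions = {}, {}
        for rec in records:
            if rec.sv_id not in panel_ids:
                continue
            planted = planted_by_pos[(rec.start, rec.end)]
            f = float(planted.breed_freqs.sum(axis=1).mean())
            marker = f"sv_{rec.sv_id}"
            sv_cols[marker] = rng.binomial(2, np.clip(f, 0.02, 0.98),
                                           size=len(snp))
            positions[marker] = rec.start
        sv_dos = pd.DataFrame(sv_cols, index=snp.index)

        # pick the causal deletion: intermediate frequency, convertible
        freqs = {m: sv_dos[m].mean() / 2 for m in sv_dos.columns}
        causal = min(freqs, key=lambda m: abs(freqs[m] - 0.5))

        G = assoc.compute_grm(snp.to_numpy())
        pheno, _ = sd.simulate_phenotypes(sv_dos, G, cfg,
                                          causal_marker=causal,
                                          seed=seed + 211)
        y = pheno["dyd"].to_numpy()
        D = np.diag(1.0 / pheno["weight"].to_numpy())

        # tested panel: SNPs (spread over a virtual 60 Mb map) + SV markers
        snp_pos = {m: int(p) for m, p in zip(
            snp.columns,
            np.sort(np.random.default_rng(seed + 307)
                    .integers(0, 60_000_000, cfg.n_snps)))}
        positions.update(snp_pos)
        panel = pd.concat([snp, sv_dos], axis=1)

        null = assoc.fit_null_reml(y, G, D)
        scan = assoc.mlma_scan(
            y, panel.to_numpy(), G, null.sigma_u2, null.sigma_e2, D,
            marker_ids=list(panel.columns),
            positions=np.array([positions[m] for m in panel.columns]))
        _, neglog = assoc.bonferroni(0.05, len(scan))
        regions = assoc.group_qtl(scan, panel.to_numpy(), neglog)
        return PipelineResult(
            truth=truth, partition=part, records=records, nrs_nodes=nrs,
            nrui_nodes=nrui, virtual_snps=vsnps, causal_sv=causal,
            null_model=null, scan=scan, threshold_neglog10=neglog,
            qtl_regions=regions, marker_positions=positions)

    if work_dir is None:
        with TemporaryDirectory() as tmp:
            return _body(Path(tmp))
    Path(work_dir).mkdir(parents=True, exist_ok=True)
    return _body(Path(work_dir))
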