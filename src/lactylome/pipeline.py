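"""End-to-end pipeline: simulate -> quantify -> differential -> catalog ->
motif -> network -> enrichment, with a machine-readable run report.

Every output is TSV/JSON with a '#' metadata header echoing the
configuration; the whole chain is a pure function of the configuration
(including the seed), so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import catalog as catalog_mod
from . import io as io_mod
from . import motif as motif_mod
from . import network as network_mod
from .differential import DifferentialModel, UP, DOWN
from .enrich import gsea_preranked, ora_hypergeometric
from .quantify import quantify_pipeline
from .simulate import (SyntheticDesign, generate_gene_sets, generate_intensities,
                       generate_lactylome, generate_ppi_graph, generate_proteome)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic-data run."""

    seed: int = 0
    outdir: str = "lactylome_run"
    # synthetic design
    n_proteins: int = 1000
    mean_length: int = 450
    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    # thresholds
    up_threshold: float = 1.5
    down_threshold: float | None = None  # None -> 1 / up_threshold
    alpha: float = 0.05
    gate_alpha: float = 0.05
    # motif block
    motif_w: int = 10
    motif_p_threshold: float = 1e-6
    motif_min_occurrences: int = 20
    # network block
    mcode_node_score_cutoff: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    ppi_clusters: tuple[tuple[int, float], ...] = ((15, 0.9), (15, 0.9), (15, 0.9))
    ppi_p_out: float = 0.02
    ppi_n_nodes: int = 60
    # enrichment block
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (10, 40)
    gsea_permutations: int = 500

    def __post_init__(self) -> None:
        if self.motif_w < 1:
            raise ValueError("motif window half-width must be >= 1")
        self.design = dataclasses.replace(self.design, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        design = SyntheticDesign(**raw.pop("design", {}))
        if "ppi_clusters" in raw:
            raw["ppi_clusters"] = tuple(tuple(c) for c in raw["ppi_clusters"])
        if "gene_set_size" in raw:
            raw["gene_set_size"] = tuple(raw["gene_set_size"])
        return cls(design=design, **raw)

    def echo(self) -> list[str]:
        cfg = dataclasses.asdict(self)
        cfg.pop("outdir")  # a location, not an analysis parameter
        return [f"lactylome {__version__}",
                f"config: {json.dumps(cfg, sort_keys=True, default=str)}"]


@dataclass
class RunReport:
    """Per-stage record counts of a pipeline run."""

    seed: int
    version: str = __version__
    n_proteins: int = 0
    n_modified_proteins: int = 0
    n_sites: int = 0
    orphan_sites_dropped: int = 0
    untestable: int = 0
    up_sites: int = 0
    down_sites: int = 0
    ns_sites: int = 0
    up_proteins: int = 0
    down_proteins: int = 0
    single_site_fraction_pct: float = 0.0
    clusters_found: int = 0
    motifs_found: int = 0
    config_echo: str = ""

    def consistent(self) -> bool:
        return (self.up_sites + self.down_sites + self.ns_sites
                + self.untestable == self.n_sites - self.orphan_sites_dropped)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full synthetic-data analysis chain and write all outputs."""
    outdir = io_mod.ensure_dir(config.outdir)
    echo = config.echo()
    report = RunReport(seed=config.seed, config_echo=echo[1])

    # --- simulate -----------------------------------------------------------
    logger.info("[simulate] generating proteome and lactylome")
    proteome = generate_proteome(config.n_proteins, config.mean_length,
                                 seed=config.seed)
    sequences = {r.accession: r.sequence for r in proteome}
    cat = generate_lactylome(proteome, config.design, w=config.motif_w)
    report.n_proteins = len(proteome)
    report.n_modified_proteins = len(cat.proteins)
    report.n_sites = len(cat)
    io_mod.write_fasta(proteome, outdir / "proteome.fasta")
    io_mod.write_site_catalog_tsv(cat, outdir / "sites.tsv", comments=echo)
    design = config.design.group_design()
    io_mod.write_design_tsv(design, outdir / "design.tsv")

    if len(cat) == 0:
        (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
        return report

    site_raw, prot_raw, truth = generate_intensities(cat, config.design)
    io_mod.write_intensity_tsv(site_raw, outdir / "site_intensities.tsv", echo)
    io_mod.write_intensity_tsv(prot_raw, outdir / "protein_intensities.tsv", echo)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # --- quantify + differential -------------------------------------------
    logger.info("[quantify] correcting %d sites by protein abundance", len(cat))
    site_map = cat.site_protein_map()
    corrected = quantify_pipeline(site_raw, prot_raw, site_map, design)
    report.orphan_sites_dropped = len(site_raw) - len(corrected)
    io_mod.write_intensity_tsv(corrected, outdir / "corrected.tsv", echo)

    logger.info("[diff] two-group testing")
    model = DifferentialModel(corrected, design,
                              up_threshold=config.up_threshold,
                              down_threshold=config.down_threshold,
                              alpha=config.alpha, gate_alpha=config.gate_alpha,
                              feature_map=site_map)
    results = model.fit()
    counts = results.counts
    report.untestable = counts["untestable"]
    report.up_sites = counts["up"]
    report.down_sites = counts["down"]
    report.ns_sites = counts["ns"]
    report.up_proteins = len(results.changed_proteins(UP))
    report.down_proteins = len(results.changed_proteins(DOWN))
    with open(outdir / "differential.tsv", "w", encoding="utf-8") as fh:
        for line in echo:
            fh.write(f"# {line}\n")
        results.table.to_csv(fh, sep="\t", float_format="%.6g")
    with open(outdir / "volcano.tsv", "w", encoding="utf-8") as fh:
        for line in echo:
            fh.write(f"# {line}\n")
        results.volcano_frame().to_csv(fh, sep="\t", float_format="%.6g")

    # --- catalog ------------------------------------------------------------
    logger.info("[catalog] summarizing site catalog")
    counts_per_protein = catalog_mod.sites_per_protein(cat)
    hist = catalog_mod.binned_site_histogram(counts_per_protein)
    hist.rename_axis("n_sites_bin").to_csv(outdir / "site_histogram.tsv", sep="\t")
    report.single_site_fraction_pct = catalog_mod.fraction_single_site(cat)
    up_prot = results.changed_proteins(UP)
    prot_results = DifferentialModel(
        _protein_relative(prot_raw), design,
        up_threshold=config.up_threshold, down_threshold=config.down_threshold,
        alpha=config.alpha, gate_alpha=config.gate_alpha).fit()
    content_changed = set(prot_results.changed_features())
    venn = catalog_mod.overlap_changed(up_prot, content_changed)
    pd.DataFrame([{"n_overlap": venn[0], "n_kla_only": venn[1],
                   "percent_kla_only": venn[2]}]).to_csv(
        outdir / "venn_up_vs_content.tsv", sep="\t", index=False)

    # --- motif --------------------------------------------------------------
    logger.info("[motif] positional frequency and motif search")
    fg_windows = cat.windows()
    bg_windows = motif_mod.proteome_background_windows(sequences, w=config.motif_w)
    fg_pfm = motif_mod.position_frequency_matrix(fg_windows, config.motif_w)
    bg_pfm = motif_mod.position_frequency_matrix(bg_windows, config.motif_w)
    fg_pfm.frequencies().rename_axis("residue").to_csv(
        outdir / "pfm_foreground.tsv", sep="\t", float_format="%.6g")
    enrichment = motif_mod.positional_enrichment(fg_pfm, bg_pfm)
    enrichment.to_csv(outdir / "positional_enrichment.tsv", sep="\t",
                      index=False, float_format="%.6g")
    motifs = motif_mod.motif_x_search(
        fg_windows, bg_windows, w=config.motif_w,
        p_threshold=config.motif_p_threshold,
        min_occurrences=config.motif_min_occurrences)
    report.motifs_found = len(motifs)
    with open(outdir / "motifs.tsv", "w", encoding="utf-8") as fh:
        fh.write("pattern\tfg_matches\tbg_matches\tfold_enrichment\tp\n")
        for m in motifs:
            fh.write(f"{m.pattern_string(config.motif_w)}\t{m.fg_matches}\t"
                     f"{m.bg_matches}\t{m.fold_enrichment:.4g}\t{m.p:.4g}\n")

    # --- network ------------------------------------------------------------
    logger.info("[network] planted PPI graph and MCODE")
    graph = generate_ppi_graph(config.ppi_n_nodes, list(config.ppi_clusters),
                               config.ppi_p_out, seed=config.seed)
    io_mod.write_edge_list_tsv(graph, outdir / "ppi_edges.tsv", echo)
    clusters = network_mod.mcode_find_complexes(
        graph, node_score_cutoff=config.mcode_node_score_cutoff,
        haircut=config.mcode_haircut, fluff=config.mcode_fluff)
    report.clusters_found = len(clusters)
    with open(outdir / "mcode_clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("cluster\tscore\tsize\tmembers\n")
        for i, cl in enumerate(clusters, start=1):
            fh.write(f"{i}\t{cl.score:.4g}\t{len(cl)}\t"
                     + ";".join(cl.sorted_members()) + "\n")

    # --- enrichment ---------------------------------------------------------
    logger.info("[enrich] ORA and preranked GSEA")
    universe = set(cat.proteins)
    sets = generate_gene_sets(sorted(universe), config.n_gene_sets,
                              config.gene_set_size, seed=config.seed)
    io_mod.write_gmt(sets, outdir / "gene_sets.gmt")
    changed = results.changed_proteins()
    if changed:
        ora = ora_hypergeometric(changed, universe, sets)
        ora.to_csv(outdir / "ora.tsv", sep="\t", index=False, float_format="%.6g")
    metric = _protein_metric(results.table, site_map)
    gsea = gsea_preranked(metric, sets, n_permutations=config.gsea_permutations,
                          seed=config.seed)
    with open(outdir / "gsea.tsv", "w", encoding="utf-8") as fh:
        fh.write("set\tsize\tes\tnes\tp\tfdr_q\n")
        for r in gsea:
            fh.write(f"{r.set_name}\t{r.size}\t{r.es:.4g}\t{r.nes:.4g}\t"
                     f"{r.p:.4g}\t{r.fdr_q:.4g}\n")

    (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    if not report.consistent():
        raise RuntimeError("internal count inconsistency in run report")
    return report


def _protein_relative(prot_raw: pd.DataFrame) -> pd.DataFrame:
    from .quantify import center_features, normalize_samples
    return center_features(normalize_samples(prot_raw))


def _protein_metric(diff_table: pd.DataFrame, site_map: pd.Series) -> pd.Series:
    """Per-protein GSEA ranking metric: site log2fc of largest magnitude."""
    frame = diff_table[["log2fc"]].copy()
    frame["protein"] = pd.Series(site_map).reindex(frame.index)
    frame = frame.dropna()
    idx = frame.groupby("protein")["log2fc"].apply(lambda s: s.abs().idxmax())
    metric = frame.loc[idx.to_numpy(), ["protein", "log2fc"]].set_index("protein")["log2fc"]
    metric.index.name = None
    return metric
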