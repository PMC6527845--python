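"""End-to-end pipeline: corpus scoring, probe reannotation, expression
normalization, differential expression, rank aggregation and the
drug-gene connectivity map, with a markdown run report.

Every stage is a call into the corresponding library module; this file
only wires them together and counts records, so the CLI stays a thin
shell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregate, connectivity, de, probes, scoring, synth
from .config import PipelineConfig
from .corpus import annotate_corpus
from .expression import ExpressionDataset

__all__ = ["PipelineResult", "run_end_to_end"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    gene_ranking: list[tuple[str, float, int]]
    drug_ranking: list[tuple[str, float, int]]
    probe_map: probes.ProbeGeneMap
    de_tables: dict[str, pd.DataFrame]
    ar_up: pd.DataFrame
    ar_down: pd.DataFrame
    connectivity_table: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)

    def top_theta(self, k: int = 5, min_support: int = 2) -> pd.DataFrame:
        """Top-k pairs by theta among pairs co-occurring in at least
        ``min_support`` abstracts.

        The regularized log-odds explodes for rare-rare pairs seen
        together once by chance, so the human-readable shortlist
        requires minimal literature support; the full table keeps every
        pair.
        """
        table = self.connectivity_table
        return table[table["df_gd"] >= min_support].nlargest(k, "theta")


def run_end_to_end(
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    synth_config: synth.SynthConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole pipeline on synthetic inputs and write its outputs.

    Generates a corpus, expression datasets and a probe fixture from
    ``synth_config`` (default conditions, overriding the seed with
    ``seed``), then scores entities, reannotates probes, runs the
    tumor-vs-normal contrast per dataset, aggregates ranks in both
    directions, and builds the connectivity map. Deterministic given the
    seed. Outputs (TSVs plus ``report.md``) go to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    scfg = synth_config or synth.SynthConfig(seed=seed)

    # --- literature stage
    bundle = synth.generate_corpus(scfg, out_dir / "inputs")
    lex = bundle.lexicons
    annotations = annotate_corpus(
        bundle.abstracts, lex["disease"], lex["gene"], lex["drug"]
    )
    gene_ranking = scoring.rank_candidates(
        annotations, "gene", cfg.weights, cfg.min_score
    )
    drug_ranking = scoring.rank_candidates(
        annotations, "drug", cfg.weights, cfg.min_score
    )
    _write_ranking(gene_ranking, out_dir / "gene_scores.tsv")
    _write_ranking(drug_ranking, out_dir / "drug_scores.tsv")

    # --- probe reannotation stage
    psl_text, gtf_text, probe_truth = synth.generate_probe_fixture(
        scfg, out_dir / "inputs"
    )
    alignments = probes.read_psl(out_dir / "inputs" / "probes.psl")
    gene_models = probes.read_gtf(out_dir / "inputs" / "genes.gtf")
    probe_map = probes.reannotate(
        alignments,
        gene_models,
        max_mismatch=cfg.max_mismatch,
        max_gap=cfg.max_gap,
        min_similarity=cfg.min_similarity,
        min_perfect_adjacent=cfg.min_perfect_adjacent,
        adjacency_gap_bp=cfg.adjacency_gap_bp,
    )
    probes.write_probe_gene_map(probe_map, out_dir / "probe_gene_map.tsv")

    # --- expression stage (generated gene-level and log2)
    datasets, expr_truth = synth.generate_expression(scfg)
    de_tables: dict[str, pd.DataFrame] = {}
    for ds in datasets:
        table = de.differential_expression(ds, "tumor_vs_normal")
        de_tables[ds.dataset_id] = table
        table.to_csv(out_dir / f"de_{ds.dataset_id}.tsv", sep="\t",
                     index=False)
    ar_up = aggregate.aggregate_datasets(de_tables, "up")
    ar_down = aggregate.aggregate_datasets(de_tables, "down")
    ar_up.to_csv(out_dir / "ar_up.tsv", sep="\t", index=False)
    ar_down.to_csv(out_dir / "ar_down.tsv", sep="\t", index=False)

    # --- connectivity stage
    matrices = [ds.matrix for ds in datasets]
    conn = connectivity.build_connectivity_matrix(
        annotations,
        gene_list=scfg.corpus_genes,
        drug_list=scfg.drugs,
        drug_targets=bundle.drug_targets,
        datasets=matrices,
        lam=cfg.lam,
    )
    conn.to_csv(out_dir / "connectivity.tsv", sep="\t", index=False)

    n_sig = sum(
        len(de.significant_genes(t, cfg.alpha)) for t in de_tables.values()
    )
    result = PipelineResult(
        gene_ranking=gene_ranking,
        drug_ranking=drug_ranking,
        probe_map=probe_map,
        de_tables=de_tables,
        ar_up=ar_up,
        ar_down=ar_down,
        connectivity_table=conn,
        stage_counts={
            "abstracts_scanned": len(bundle.abstracts),
            "genes_above_threshold": len(gene_ranking),
            "drugs_above_threshold": len(drug_ranking),
            "probes_aligned": len(alignments),
            "probes_assigned": len(probe_map.assignments),
            "expression_datasets": len(datasets),
            "genes_per_dataset": len(datasets[0].matrix) if datasets else 0,
            "significant_tests_total": n_sig,
            "connectivity_pairs": len(conn),
        },
    )
    (out_dir / "report.md").write_text(_render_report(result, seed))
    return result


def _write_ranking(ranking, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\ttotal_score\tn_abstracts\n")
        for entity, total, n in ranking:
            fh.write(f"{entity}\t{total:g}\t{n}\n")


def _render_report(result: PipelineResult, seed: int) -> str:
    lines = [
        "# cmapminer pipeline report",
        "",
        f"seed: {seed}",
        "",
        "## Stage counts",
        "",
    ]
    for key, value in result.stage_counts.items():
        lines.append(f"- {key}: {value}")
    lines += ["", "## Top genes by total association score", ""]
    for entity, total, n in result.gene_ranking[:10]:
        lines.append(f"- {entity}: score {total:g} over {n} abstracts")
    lines += ["", "## Top connectivity pairs (theta)", ""]
    for _, row in result.top_theta(5).iterrows():
        lines.append(
            f"- {row['gene_id']} x {row['drug_id']}: theta {row['theta']:.3f} "
            f"(df_gd={row['df_gd']}, corr={row['corr_gd']:.2f})"
        )
    lines.append("")
    return "\n".join(lines)
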