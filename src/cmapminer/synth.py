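"""Seeded generators for every input the pipeline consumes.

Three generators emulate, at desk scale, the real inputs of the
pipeline — literature abstracts with dictionary lexicons, expression
matrices with group labels, and probe alignments with gene models —
each with ground-truth labels so recovery can be checked end to end.

Realism is deliberately minimal: abstracts are template
subject-verb-object sentences with entity slots (dictionary-matching
difficulty is not the test target), expression values are i.i.d.
Gaussian on the log2 scale apart from the planted group shifts and
planted pairwise correlations, and the probe fixture is a hand-laid toy
chromosome containing at least one decoy for every filtering rule.

Each generator draws from its own substream of the configured seed, so
adding a call to one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Abstract, Lexicon
from .expression import ExpressionDataset

__all__ = [
    "SynthConfig",
    "TruthLabels",
    "CorpusBundle",
    "generate_corpus",
    "generate_expression",
    "generate_probe_fixture",
]

_CORPUS_STREAM = 1
_EXPRESSION_STREAM = 2
_PROBE_STREAM = 3

DISEASE_SYNONYMS = (
    "head and neck cancer",
    "oral cancer",
    "HNSCC",
    "laryngeal cancer",
    "throat cancer",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic inputs.

    Corpus: ``n_planted_genes`` disease-associated genes are planted
    among ``n_background_genes`` incidental ones; a planted gene
    co-occurs with a disease term in a fraction
    ``planted_cooccurrence_rate`` of abstracts, and one planted
    drug-gene pair co-occurs at the same rate. Background entities
    appear, without disease context, at ``background_mention_rate``.

    Expression: per dataset, log2-scale baseline N(8, 1); planted genes
    are shifted by ``effect_size_log2`` (alternating sign) in tumor
    samples; one designated gene pair is generated as y = x + N(0,
    planted_corr_sigma^2), giving population correlation
    1/sqrt(1 + sigma^2).
    """

    seed: int = 0
    n_abstracts: int = 200
    n_background_genes: int = 50
    n_planted_genes: int = 5
    n_drugs: int = 10
    planted_cooccurrence_rate: float = 0.2
    background_mention_rate: float = 0.3
    sentences_per_abstract: tuple[int, int] = (3, 6)
    n_datasets: int = 5
    genes_per_dataset: int = 200
    samples_per_group: int = 10
    effect_size_log2: float = 2.0
    noise_sd: float = 1.0
    planted_corr_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("planted_cooccurrence_rate", "background_mention_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "n_abstracts", "n_background_genes", "n_planted_genes",
            "n_drugs", "n_datasets", "genes_per_dataset",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_planted_genes > self.n_background_genes + self.n_planted_genes:
            raise ValueError("planted genes must be a subset of all genes")

    @property
    def gene_pool(self) -> list[str]:
        n = max(self.n_background_genes + self.n_planted_genes,
                self.genes_per_dataset)
        return [f"G{i:03d}" for i in range(1, n + 1)]

    @property
    def corpus_genes(self) -> list[str]:
        return self.gene_pool[: self.n_background_genes + self.n_planted_genes]

    @property
    def planted_genes(self) -> list[str]:
        return self.corpus_genes[: self.n_planted_genes]

    @property
    def background_genes(self) -> list[str]:
        return self.corpus_genes[self.n_planted_genes:]

    @property
    def drugs(self) -> list[str]:
        return [f"DRUG{i:02d}" for i in range(1, self.n_drugs + 1)]

    @property
    def planted_pair(self) -> tuple[str, str] | None:
        """(drug_id, gene_id) of the planted drug-gene association."""
        if not self.drugs or not self.planted_genes:
            return None
        return self.drugs[0], self.planted_genes[0]

    @property
    def correlated_pair(self) -> tuple[str, str]:
        """(x_gene, y_gene) generated with the planted correlation."""
        pool = self.gene_pool
        return pool[-2], pool[-1]


@dataclass
class TruthLabels:
    """Ground truth attached to a generated input."""

    planted_gene_ids: list[str] = field(default_factory=list)
    planted_drug_gene_pairs: list[tuple[str, str]] = field(default_factory=list)
    de_gene_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    probe_truth_map: dict[str, str] = field(default_factory=dict)
    probe_drop_reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class CorpusBundle:
    abstracts: list[Abstract]
    lexicons: dict[str, Lexicon]
    drug_targets: dict[str, set[str]]
    truth: TruthLabels


def _corpus_lexicons(cfg: SynthConfig) -> dict[str, Lexicon]:
    disease = Lexicon("disease", {"DIS:HNC": set(DISEASE_SYNONYMS)})
    genes = Lexicon(
        "gene", {g: {g, f"{g} protein"} for g in cfg.corpus_genes}
    )
    drugs = Lexicon("drug", {d: {d} for d in cfg.drugs})
    return {"disease": disease, "gene": genes, "drug": drugs}


def generate_corpus(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> CorpusBundle:
    """Generate a toy abstract corpus with planted associations.

    Sentence templates: planted genes appear in disease co-occurrence
    sentences; the planted drug-gene pair co-occurs in one sentence;
    background genes and drugs appear in disease-free context sentences;
    filler and disease-only sentences pad each abstract to its length.
    """
    rng = np.random.default_rng([_CORPUS_STREAM, cfg.seed])
    lexicons = _corpus_lexicons(cfg)
    truth = TruthLabels(planted_gene_ids=list(cfg.planted_genes))
    if cfg.planted_pair is not None:
        truth.planted_drug_gene_pairs = [cfg.planted_pair]

    drug_targets: dict[str, set[str]] = {}
    if cfg.planted_pair is not None:
        drug, gene = cfg.planted_pair
        drug_targets[drug] = {gene}
    for d in cfg.drugs[1:]:
        if cfg.corpus_genes:
            drug_targets[d] = {str(rng.choice(cfg.background_genes or
                                              cfg.corpus_genes))}

    abstracts: list[Abstract] = []
    lo, hi = cfg.sentences_per_abstract
    for i in range(cfg.n_abstracts):
        sentences: list[str] = []
        n_target = int(rng.integers(lo, hi + 1))
        if cfg.planted_genes and rng.random() < cfg.planted_cooccurrence_rate:
            pg = str(rng.choice(cfg.planted_genes))
            disease_term = str(rng.choice(DISEASE_SYNONYMS[:2]))
            sentences.append(
                f"In {disease_term}, {pg} is frequently overexpressed."
            )
        if cfg.planted_pair is not None and (
            rng.random() < cfg.planted_cooccurrence_rate
        ):
            drug, gene = cfg.planted_pair
            sentences.append(
                f"{drug} inhibits {gene} in patients with oral cancer."
            )
        if rng.random() < 0.7:
            sentences.append(
                "Head and neck cancer remains a major clinical challenge."
            )
        if cfg.background_genes and rng.random() < cfg.background_mention_rate:
            bg = str(rng.choice(cfg.background_genes))
            sentences.append(
                f"The expression of {bg} was measured in cell lines."
            )
        if cfg.drugs and rng.random() < cfg.background_mention_rate:
            d = str(rng.choice(cfg.drugs))
            sentences.append(f"Patients received {d} as part of therapy.")
        while len(sentences) < n_target:
            sentences.append(
                "The samples were processed using standard protocols."
            )
        rng.shuffle(sentences)
        abstracts.append(Abstract(f"PMID{i + 1:06d}", " ".join(sentences)))

    bundle = CorpusBundle(abstracts, lexicons, drug_targets, truth)
    if out_dir is not None:
        _write_corpus(bundle, Path(out_dir))
    return bundle


def _write_corpus(bundle: CorpusBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "corpus.tsv", "w") as fh:
        fh.write("abstract_id\ttext\n")
        for a in bundle.abstracts:
            fh.write(f"{a.abstract_id}\t{a.text}\n")
    with open(out_dir / "lexicon.tsv", "w") as fh:
        fh.write("canonical_id\tcategory\tsynonym\n")
        for category in sorted(bundle.lexicons):
            lex = bundle.lexicons[category]
            for cid in sorted(lex.entries):
                for syn in sorted(lex.entries[cid]):
                    fh.write(f"{cid}\t{category}\t{syn}\n")
    with open(out_dir / "drug_targets.tsv", "w") as fh:
        fh.write("drug_id\tgene_id\n")
        for drug in sorted(bundle.drug_targets):
            for gene in sorted(bundle.drug_targets[drug]):
                fh.write(f"{drug}\t{gene}\n")


def generate_expression(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[ExpressionDataset], TruthLabels]:
    """Generate gene-level log2 expression datasets with planted effects.

    Planted genes are shifted in the tumor group by ``effect_size_log2``
    with alternating sign (even-indexed up, odd-indexed down); the
    designated correlated pair is generated as y = x + N(0, sigma^2).
    HPV and smoking labels are assigned at random (no planted effect) so
    the secondary contrasts are exercised under the null.
    """
    if cfg.samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2")
    rng = np.random.default_rng([_EXPRESSION_STREAM, cfg.seed])
    truth = TruthLabels(planted_gene_ids=list(cfg.planted_genes))
    genes = cfg.gene_pool[: cfg.genes_per_dataset]
    x_gene, y_gene = cfg.correlated_pair
    datasets: list[ExpressionDataset] = []
    for d in range(cfg.n_datasets):
        dataset_id = f"SYN{d + 1:03d}"
        n = cfg.samples_per_group
        samples = [f"{dataset_id}.S{j + 1:03d}" for j in range(2 * n)]
        groups = ["tumor"] * n + ["normal"] * n
        values = rng.normal(8.0, cfg.noise_sd, size=(len(genes), 2 * n))
        matrix = pd.DataFrame(values, index=genes, columns=samples)
        effects: dict[str, float] = {}
        for k, pg in enumerate(cfg.planted_genes):
            if pg not in matrix.index:
                continue
            sign = 1.0 if k % 2 == 0 else -1.0
            effect = sign * cfg.effect_size_log2
            matrix.loc[pg, matrix.columns[:n]] += effect
            effects[pg] = effect
        if x_gene in matrix.index and y_gene in matrix.index:
            noise = rng.normal(0.0, cfg.planted_corr_sigma, size=2 * n)
            matrix.loc[y_gene] = matrix.loc[x_gene].to_numpy() + noise
            truth.correlated_pairs.append(
                (x_gene, y_gene, cfg.planted_corr_sigma)
            )
        truth.de_gene_effects[dataset_id] = effects
        metadata = pd.DataFrame(
            {
                "group": groups,
                "hpv": rng.choice(
                    ["positive", "negative", "unknown"], size=2 * n,
                    p=[0.4, 0.4, 0.2],
                ),
                "smoking": rng.choice(
                    ["smoker", "non-smoker", "unknown"], size=2 * n,
                    p=[0.4, 0.4, 0.2],
                ),
            },
            index=pd.Index(samples, name="sample_id"),
        )
        datasets.append(
            ExpressionDataset(dataset_id, matrix, metadata, is_log2=True)
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ds in datasets:
            ds.matrix.round(6).to_csv(
                out_dir / f"{ds.dataset_id}.matrix.tsv", sep="\t"
            )
            ds.metadata.to_csv(out_dir / f"{ds.dataset_id}.meta.tsv", sep="\t")
    return datasets, truth


# ---------------------------------------------------------------------------
# Probe fixture: a hand-laid toy chromosome. Every filtering rule has a
# decoy violating exactly that rule; the truth map records the intended
# assignment or drop reason for each feature.

_FIXTURE_GENES = [
    # (gene_id, biotype, start, end, strand) -- 0-based half-open
    ("C1", "coding", 1_000, 2_000, "+"),
    ("L1", "lncRNA", 3_000, 4_000, "+"),
    ("C2", "coding", 5_000, 6_000, "+"),
    ("L2", "lncRNA", 5_500, 6_500, "+"),
    ("C3", "coding", 8_000, 9_000, "+"),
    ("C4", "coding", 10_000, 11_000, "+"),
    ("C5", "coding", 10_800, 11_800, "+"),
    ("C6", "coding", 13_000, 14_000, "+"),
    ("C7", "coding", 15_000, 16_000, "-"),
    ("C8", "coding", 17_000, 18_500, "+"),
]

_FIXTURE_PROBES = [
    # (qName, qSize, matches, mismatches, gaps, start, end, strand)
    ("pOK", 60, 60, 0, 0, 1_100, 1_160, "+"),
    ("pLNC", 60, 60, 0, 0, 3_100, 3_160, "+"),
    ("pPRIO", 60, 60, 0, 0, 5_600, 5_660, "+"),
    ("pMM2", 60, 58, 2, 0, 1_200, 1_260, "+"),
    ("pGAP", 60, 59, 0, 1, 1_300, 1_361, "+"),
    ("pLOWSIM", 60, 54, 0, 0, 1_400, 1_454, "+"),
    ("pAMB", 60, 60, 0, 0, 10_850, 10_910, "+"),
    ("pMULTI", 60, 60, 0, 0, 1_500, 1_560, "+"),
    ("pMULTI", 60, 60, 0, 0, 13_100, 13_160, "+"),
    ("pSTRAND", 60, 60, 0, 0, 15_100, 15_160, "+"),
    # AF1: four perfect adjacent 25-mers inside C3 -> retained
    ("AF1:p1", 25, 25, 0, 0, 8_100, 8_125, "+"),
    ("AF1:p2", 25, 25, 0, 0, 8_150, 8_175, "+"),
    ("AF1:p3", 25, 25, 0, 0, 8_200, 8_225, "+"),
    ("AF1:p4", 25, 25, 0, 0, 8_250, 8_275, "+"),
    # AF2: only two perfect probes -> dropped at collapsing
    ("AF2:p1", 25, 25, 0, 0, 17_100, 17_125, "+"),
    ("AF2:p2", 25, 25, 0, 0, 17_150, 17_175, "+"),
    ("AF2:p3", 25, 24, 1, 0, 17_200, 17_225, "+"),
    # AF3: three perfect probes too far apart -> dropped at collapsing
    ("AF3:p1", 25, 25, 0, 0, 17_400, 17_425, "+"),
    ("AF3:p2", 25, 25, 0, 0, 17_800, 17_825, "+"),
    ("AF3:p3", 25, 25, 0, 0, 18_300, 18_325, "+"),
]

_FIXTURE_TRUTH = {
    "pOK": "C1",
    "pLNC": "L1",
    "pPRIO": "C2",
    "AF1": "C3",
}

_FIXTURE_DROPS = {
    "pMM2": "filtered:mismatch",
    "pGAP": "filtered:gap",
    "pLOWSIM": "filtered:similarity",
    "pAMB": "ambiguous",
    "pMULTI": "multimapping",
    "pSTRAND": "no_overlap",
    "AF2": "collapse_failed",
    "AF3": "collapse_failed",
}

_FIXTURE_CHROM = "chr1"
_FIXTURE_CHROM_SIZE = 30_000_000


def generate_probe_fixture(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[str, str, TruthLabels]:
    """Build the probe-reannotation fixture as (PSL text, GTF text, truth).

    The layout is deterministic; the seed only shuffles line order of
    the PSL body (parsing and assignment must not depend on it).
    """
    rng = np.random.default_rng([_PROBE_STREAM, cfg.seed])
    psl_lines = []
    for (qname, qsize, matches, mism, gaps, start, end, strand) in _FIXTURE_PROBES:
        gap_bases = end - start - (matches + mism)
        fields = [
            matches, mism, 0, 0,          # matches misMatches repMatches nCount
            gaps, 0, 0, max(gap_bases, 0),  # q/t insert counts and bases
            strand, qname, qsize, 0, qsize,
            _FIXTURE_CHROM, _FIXTURE_CHROM_SIZE, start, end,
            1, f"{end - start},", "0,", f"{start},",
        ]
        psl_lines.append("\t".join(str(f) for f in fields))
    order = rng.permutation(len(psl_lines))
    psl_text = "\n".join(psl_lines[i] for i in order) + "\n"

    gtf_lines = []
    for gene_id, biotype, start, end, strand in _FIXTURE_GENES:
        bt = "protein_coding" if biotype == "coding" else "lncRNA"
        gtf_lines.append(
            f"{_FIXTURE_CHROM}\tsynth\tgene\t{start + 1}\t{end}\t.\t{strand}"
            f'\t.\tgene_id "{gene_id}"; gene_biotype "{bt}";'
        )
    gtf_text = "\n".join(gtf_lines) + "\n"

    truth = TruthLabels(
        probe_truth_map=dict(_FIXTURE_TRUTH),
        probe_drop_reasons=dict(_FIXTURE_DROPS),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "probes.psl").write_text(psl_text)
        (out_dir / "genes.gtf").write_text(gtf_text)
    return psl_text, gtf_text, truth
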