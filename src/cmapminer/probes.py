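"""Microarray probe reannotation from genomic alignments.

Probes (or Affymetrix probe sets) aligned to the genome are filtered on
alignment quality — at most one mismatch, no gaps, similarity above 90 —
and assigned to the gene whose span they fall in, with coding genes
taking priority over lncRNAs and ambiguous or multi-mapping probes
dropped. Input is BLAT's 21-column PSL format; gene models come from
BED or GTF. All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "ProbeAlignment",
    "GeneModel",
    "ProbeGeneMap",
    "read_psl",
    "read_bed",
    "read_gtf",
    "filter_alignments",
    "collapse_affymetrix_probesets",
    "assign_genes",
    "reannotate",
    "write_probe_gene_map",
    "write_bed12",
]

PSL_COLUMNS = 21
#: qName of the form "<probe_set_id>:<probe_id>" marks an Affymetrix probe.
PROBE_SET_DELIMITER = ":"


@dataclass(frozen=True)
class ProbeAlignment:
    """One genomic alignment of a probe (0-based half-open coordinates)."""

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str
    matches: int
    mismatches: int
    gap_count: int
    query_size: int
    probe_set_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.probe_id}: start must be < end")
        if min(self.matches, self.mismatches, self.gap_count) < 0:
            raise ValueError(f"{self.probe_id}: negative alignment counts")
        if self.matches + self.mismatches > self.query_size:
            raise ValueError(
                f"{self.probe_id}: matches + mismatches exceed query size"
            )

    @property
    def feature_id(self) -> str:
        return self.probe_set_id if self.probe_set_id is not None else self.probe_id

    def similarity(self) -> float:
        """Percent of the probe sequence aligned as a match (0-100)."""
        return 100.0 * self.matches / self.query_size


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    biotype: str  # "coding" or "lncRNA"
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.biotype not in ("coding", "lncRNA"):
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")


@dataclass
class ProbeGeneMap:
    """Resolved feature -> gene assignment with per-feature provenance.

    ``assignments`` maps each kept feature to exactly one gene.
    ``provenance`` records, for every input feature, the number of
    candidate genes, whether the coding-over-lncRNA priority decided the
    call, and — for dropped features — the reason
    (``multimapping``, ``ambiguous``, ``no_overlap``).
    """

    assignments: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def dropped(self, reason: str | None = None) -> set[str]:
        return {
            f
            for f, p in self.provenance.items()
            if "drop_reason" in p
            and (reason is None or p["drop_reason"] == reason)
        }


def _parse_psl_line(line: str, lineno: int) -> ProbeAlignment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != PSL_COLUMNS:
        raise ValueError(
            f"PSL line {lineno}: expected {PSL_COLUMNS} columns, "
            f"got {len(fields)}"
        )
    try:
        matches = int(fields[0])
        mismatches = int(fields[1])
        q_num_insert = int(fields[4])
        t_num_insert = int(fields[6])
        strand = fields[8]
        q_name = fields[9]
        q_size = int(fields[10])
        t_name = fields[13]
        t_start = int(fields[15])
        t_end = int(fields[16])
    except ValueError as exc:
        raise ValueError(f"PSL line {lineno}: {exc}") from None
    probe_set_id = None
    probe_id = q_name
    if PROBE_SET_DELIMITER in q_name:
        probe_set_id, _, _ = q_name.partition(PROBE_SET_DELIMITER)
    return ProbeAlignment(
        probe_id=probe_id,
        chrom=t_name,
        start=t_start,
        end=t_end,
        strand=strand,
        matches=matches,
        mismatches=mismatches,
        gap_count=q_num_insert + t_num_insert,
        query_size=q_size,
        probe_set_id=probe_set_id,
    )


def read_psl(path: str | Path) -> list[ProbeAlignment]:
    """Parse a PSL file (optional 5-line header auto-detected)."""
    alignments: list[ProbeAlignment] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5  # standard BLAT header block
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        alignments.append(_parse_psl_line(line, lineno))
    return alignments


def read_bed(path: str | Path, biotype: str = "coding") -> list[GeneModel]:
    """Read gene models from BED6/BED12.

    BED has no biotype notion; a name suffix ``|coding`` or ``|lncRNA``
    overrides the ``biotype`` default.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            bt = biotype
            if "|" in name:
                name, _, bt = name.rpartition("|")
            strand = f[5] if len(f) > 5 else "+"
            genes.append(GeneModel(name, bt, f[0], int(f[1]), int(f[2]), strand))
    return genes


_GTF_CODING = {"protein_coding", "coding"}
_GTF_LNCRNA = {"lncrna", "lincrna", "lnc_rna"}


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF ``gene`` lines.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open here, at the parser boundary. Biotype is taken from the
    ``gene_biotype`` (or ``gene_type``) attribute; biotypes other than
    protein-coding and lncRNA are skipped.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = _gtf_attributes(f[8])
            raw_bt = attrs.get("gene_biotype", attrs.get("gene_type", "")).lower()
            if raw_bt in _GTF_CODING:
                bt = "coding"
            elif raw_bt in _GTF_LNCRNA:
                bt = "lncRNA"
            else:
                continue
            genes.append(
                GeneModel(attrs["gene_id"], bt, f[0], int(f[3]) - 1, int(f[4]),
                          f[6])
            )
    return genes


def filter_alignments(
    alignments: Iterable[ProbeAlignment],
    max_mismatch: int = 1,
    max_gap: int = 0,
    min_similarity: float = 90.0,
    similarity_fn: Callable[[ProbeAlignment], float] | None = None,
) -> list[ProbeAlignment]:
    """Keep alignments with at most ``max_mismatch`` mismatches, at most
    ``max_gap`` gaps and similarity strictly above ``min_similarity``.

    Similarity defaults to percent matched bases
    (``100 * matches / query_size``); ``similarity_fn`` swaps in any
    other 0-100 definition.
    """
    sim = similarity_fn or ProbeAlignment.similarity
    return [
        a
        for a in alignments
        if a.mismatches <= max_mismatch
        and a.gap_count <= max_gap
        and sim(a) > min_similarity
    ]


def collapse_affymetrix_probesets(
    alignments: Sequence[ProbeAlignment],
    min_perfect_adjacent: int = 3,
    adjacency_gap_bp: int = 200,
) -> list[ProbeAlignment]:
    """Collapse Affymetrix probe-level alignments to probe-set records.

    A probe set is kept iff, at one genomic locus (chromosome + strand),
    it has a run of at least ``min_perfect_adjacent`` perfectly matching
    probes (no mismatches, no gaps) whose consecutive starts are within
    ``adjacency_gap_bp``. The emitted synthetic record spans the longest
    qualifying run. A set qualifying at several loci emits one record
    per locus (resolved later as multi-mapping).
    """
    by_set: dict[str, list[ProbeAlignment]] = defaultdict(list)
    for a in alignments:
        if a.probe_set_id is None:
            raise ValueError(f"probe {a.probe_id} lacks a probe_set_id")
        by_set[a.probe_set_id].append(a)

    collapsed: list[ProbeAlignment] = []
    for set_id in sorted(by_set):
        by_locus: dict[tuple[str, str], list[ProbeAlignment]] = defaultdict(list)
        for a in by_set[set_id]:
            if a.mismatches == 0 and a.gap_count == 0:
                by_locus[(a.chrom, a.strand)].append(a)
        for (chrom, strand), probes in sorted(by_locus.items()):
            probes.sort(key=lambda a: (a.start, a.end))
            best_run: list[ProbeAlignment] = []
            run: list[ProbeAlignment] = []
            for p in probes:
                if run and p.start - run[-1].start > adjacency_gap_bp:
                    run = []
                run = run + [p]
                if len(run) > len(best_run):
                    best_run = run
            if len(best_run) >= min_perfect_adjacent:
                collapsed.append(
                    ProbeAlignment(
                        probe_id=set_id,
                        chrom=chrom,
                        start=min(p.start for p in best_run),
                        end=max(p.end for p in best_run),
                        strand=strand,
                        matches=sum(p.matches for p in best_run),
                        mismatches=0,
                        gap_count=0,
                        query_size=sum(p.query_size for p in best_run),
                        probe_set_id=set_id,
                    )
                )
    return collapsed


def assign_genes(
    features: Sequence[ProbeAlignment],
    gene_models: Sequence[GeneModel],
    ignore_strand: bool = False,
) -> ProbeGeneMap:
    """Assign each feature to at most one gene by genomic overlap.

    Rules, applied per feature: a feature aligning at more than one
    locus is dropped (``multimapping``); overlap requires matching
    strand unless ``ignore_strand``; exactly one candidate gene wins;
    coding + lncRNA candidates resolve to the coding gene; two or more
    coding genes (or two or more lncRNAs with no coding gene) drop the
    feature (``ambiguous``); no overlap drops it (``no_overlap``).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in gene_models:
        trees[g.chrom].addi(g.start, g.end, g)

    by_feature: dict[str, list[ProbeAlignment]] = defaultdict(list)
    for f in features:
        by_feature[f.feature_id].append(f)

    result = ProbeGeneMap()
    for feature_id in sorted(by_feature):
        alns = by_feature[feature_id]
        if len(alns) > 1:
            result.provenance[feature_id] = {
                "n_candidates": 0,
                "coding_priority_applied": False,
                "drop_reason": "multimapping",
            }
            continue
        aln = alns[0]
        hits = [
            iv.data
            for iv in trees[aln.chrom].overlap(aln.start, aln.end)
            if ignore_strand or iv.data.strand == aln.strand
        ]
        coding = sorted({g.gene_id for g in hits if g.biotype == "coding"})
        lnc = sorted({g.gene_id for g in hits if g.biotype == "lncRNA"})
        prov: dict = {
            "n_candidates": len(coding) + len(lnc),
            "coding_priority_applied": False,
        }
        if not hits:
            prov["drop_reason"] = "no_overlap"
        elif len(coding) == 1:
            prov["coding_priority_applied"] = bool(lnc)
            result.assignments[feature_id] = coding[0]
        elif len(coding) >= 2:
            prov["drop_reason"] = "ambiguous"
        elif len(lnc) == 1:
            result.assignments[feature_id] = lnc[0]
        else:
            prov["drop_reason"] = "ambiguous"
        result.provenance[feature_id] = prov
    return result


def reannotate(
    alignments: Sequence[ProbeAlignment],
    gene_models: Sequence[GeneModel],
    platform: str = "auto",
    max_mismatch: int = 1,
    max_gap: int = 0,
    min_similarity: float = 90.0,
    min_perfect_adjacent: int = 3,
    adjacency_gap_bp: int = 200,
    ignore_strand: bool = False,
) -> ProbeGeneMap:
    """Full reannotation: filter, collapse (Affymetrix), assign.

    ``platform="affymetrix"`` collapses probe-level records into
    probe-set records before gene assignment; ``"long-oligo"``
    (Agilent/Illumina-style single probes) assigns probes directly;
    ``"auto"`` routes each record by whether it carries a probe_set_id.
    """
    kept = filter_alignments(alignments, max_mismatch, max_gap, min_similarity)
    if platform == "auto":
        affy = [a for a in kept if a.probe_set_id is not None]
        single = [a for a in kept if a.probe_set_id is None]
    elif platform == "affymetrix":
        affy, single = list(kept), []
    elif platform == "long-oligo":
        affy, single = [], list(kept)
    else:
        raise ValueError(f"unknown platform {platform!r}")
    features = single + (
        collapse_affymetrix_probesets(affy, min_perfect_adjacent,
                                      adjacency_gap_bp)
        if affy
        else []
    )
    return assign_genes(features, gene_models, ignore_strand)


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tgene_id\tn_candidates\tcoding_priority_applied\n")
        for fid in sorted(pmap.assignments):
            p = pmap.provenance[fid]
            fh.write(
                f"{fid}\t{pmap.assignments[fid]}\t{p['n_candidates']}\t"
                f"{int(p['coding_priority_applied'])}\n"
            )


def write_bed12(features: Sequence[ProbeAlignment], path: str | Path) -> None:
    """Export features as single-block BED12 (coordinates preserved)."""
    with open(path, "w") as fh:
        for f in features:
            size = f.end - f.start
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\t"
                f"{f.start}\t{f.end}\t0\t1\t{size},\t0,\n"
            )
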