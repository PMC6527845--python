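"""PSL parsing, alignment filtering, probe-set collapsing and gene
assignment."""

import itertools
import random

import pytest

from cmapminer.probes import (
    GeneModel,
    ProbeAlignment,
    assign_genes,
    collapse_affymetrix_probesets,
    filter_alignments,
    read_gtf,
    read_psl,
    reannotate,
    write_bed12,
)
from cmapminer.synth import SynthConfig, generate_probe_fixture


def aln(probe_id="p", chrom="chr1", start=100, end=160, strand="+",
        matches=60, mismatches=0, gap_count=0, query_size=60, set_id=None):
    return ProbeAlignment(probe_id, chrom, start, end, strand, matches,
                          mismatches, gap_count, query_size, set_id)


PSL_LINE = (
    "60\t0\t0\t0\t0\t0\t0\t0\t+\tprobeA\t60\t0\t60\tchr2\t1000000\t500\t560"
    "\t1\t60,\t0,\t500,\n"
)


class TestReadPsl:
    def test_header_only_file_is_empty(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text(
            "psLayout version 3\n\nmatch\tmis-\nmatch\n---------------\n"
        )
        assert read_psl(p) == []

    def test_three_line_fixture_fields(self, tmp_path):
        p = tmp_path / "x.psl"
        _, _, _ = generate_probe_fixture(SynthConfig(seed=0), tmp_path)
        records = read_psl(tmp_path / "probes.psl")
        assert len(records) == 20
        by_id = {(r.feature_id, r.start): r for r in records}
        ok = by_id[("pOK", 1100)]
        assert (ok.chrom, ok.end, ok.strand) == ("chr1", 1160, "+")
        assert (ok.matches, ok.mismatches, ok.gap_count) == (60, 0, 0)

    def test_probe_set_id_parsed_from_qname(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text(PSL_LINE.replace("probeA", "SET1:p9"))
        (rec,) = read_psl(p)
        assert rec.probe_set_id == "SET1" and rec.feature_id == "SET1"

    def test_malformed_line_names_the_line(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text(PSL_LINE + "\t".join(["1"] * 20) + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_psl(p)

    def test_coordinate_roundtrip_through_bed12(self, tmp_path):
        p = tmp_path / "x.psl"
        p.write_text(PSL_LINE)
        records = read_psl(p)
        out = tmp_path / "x.bed"
        write_bed12(records, out)
        fields = out.read_text().split("\t")
        assert (fields[1], fields[2]) == ("500", "560")


class TestFilterAlignments:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            (dict(mismatches=2, matches=58), False),   # > 1 mismatch
            (dict(mismatches=1, matches=59), True),
            (dict(gap_count=1, matches=59), False),    # any gap
            (dict(matches=54, end=154), False),        # similarity 90, not > 90
            (dict(matches=55, end=155), True),         # similarity ~91.7
        ],
    )
    def test_single_rules(self, kwargs, kept):
        result = filter_alignments([aln(**kwargs)])
        assert bool(result) == kept

    def test_fixture_survivor_count_matches_per_record_check(self):
        rng = random.Random(1)
        records = [
            aln(probe_id=f"p{i}", mismatches=(m := rng.randint(0, 2)),
                matches=rng.randint(50, 60 - m), gap_count=rng.randint(0, 1))
            for i in range(10)
        ]
        expected = [
            r for r in records
            if r.mismatches <= 1 and r.gap_count == 0
            and 100 * r.matches / r.query_size > 90
        ]
        assert filter_alignments(records) == expected

    def test_idempotent_and_order_independent(self):
        rng = random.Random(2)
        records = [
            aln(probe_id=f"p{i}", mismatches=(m := rng.randint(0, 2)),
                matches=rng.randint(50, 60 - m), gap_count=rng.randint(0, 1))
            for i in range(30)
        ]
        once = filter_alignments(records)
        assert filter_alignments(once) == once
        shuffled = records[::-1]
        assert sorted(filter_alignments(shuffled), key=lambda a: a.probe_id) \
            == sorted(once, key=lambda a: a.probe_id)

    def test_custom_similarity_hook(self):
        rec = aln(matches=54, end=154)  # default similarity exactly 90
        assert filter_alignments([rec], similarity_fn=lambda a: 95.0) == [rec]


def brute_force_collapse(records, min_run=3, gap=200):
    """Enumerate all probe subsets per set and locus; a locus qualifies if
    any subset of >= min_run perfect probes has consecutive starts within
    the adjacency gap."""
    kept = set()
    sets = {}
    for r in records:
        sets.setdefault(r.probe_set_id, []).append(r)
    for set_id, probes in sets.items():
        perfect = [p for p in probes if p.mismatches == 0 and p.gap_count == 0]
        loci = {(p.chrom, p.strand) for p in perfect}
        for locus in loci:
            here = sorted(
                (p for p in perfect if (p.chrom, p.strand) == locus),
                key=lambda p: (p.start, p.end),
            )
            for n in range(min_run, len(here) + 1):
                for combo in itertools.combinations(here, n):
                    if all(
                        combo[i + 1].start - combo[i].start <= gap
                        for i in range(n - 1)
                    ):
                        kept.add((set_id,) + locus)
                        break
    return kept


class TestCollapseProbesets:
    def test_two_perfect_probes_dropped(self):
        records = [
            aln(f"S:p{i}", start=100 + 50 * i, end=125 + 50 * i, matches=25,
                query_size=25, set_id="S")
            for i in range(2)
        ]
        assert collapse_affymetrix_probesets(records) == []

    def test_four_perfect_adjacent_retained_with_full_span(self):
        records = [
            aln(f"S:p{i}", start=100 + 50 * i, end=125 + 50 * i, matches=25,
                query_size=25, set_id="S")
            for i in range(4)
        ]
        (rec,) = collapse_affymetrix_probesets(records)
        assert (rec.feature_id, rec.start, rec.end) == ("S", 100, 275)
        assert rec.mismatches == 0 and rec.gap_count == 0

    def test_missing_probe_set_id_rejected(self):
        with pytest.raises(ValueError):
            collapse_affymetrix_probesets([aln()])

    def test_randomized_fixtures_match_bruteforce_enumeration(self):
        rng = random.Random(3)
        for _ in range(20):
            records = []
            for s in range(3):
                for i in range(rng.randint(1, 6)):
                    start = rng.randrange(0, 2000, 10)
                    mism = 0 if rng.random() < 0.8 else 1
                    records.append(
                        aln(f"S{s}:p{i}", start=start, end=start + 25,
                            matches=25 - mism, mismatches=mism,
                            query_size=25, set_id=f"S{s}",
                            strand=rng.choice("++-"))
                    )
            got = {
                (r.feature_id, r.chrom, r.strand)
                for r in collapse_affymetrix_probesets(records)
            }
            assert got == brute_force_collapse(records)


def brute_force_assign(features, genes, ignore_strand=False):
    out = {}
    by_feature = {}
    for f in features:
        by_feature.setdefault(f.feature_id, []).append(f)
    for fid, alns in by_feature.items():
        if len(alns) > 1:
            continue
        f = alns[0]
        hits = [
            g for g in genes
            if g.chrom == f.chrom and g.start < f.end and f.start < g.end
            and (ignore_strand or g.strand == f.strand)
        ]
        coding = sorted({g.gene_id for g in hits if g.biotype == "coding"})
        lnc = sorted({g.gene_id for g in hits if g.biotype == "lncRNA"})
        if len(coding) == 1:
            out[fid] = coding[0]
        elif not coding and len(lnc) == 1:
            out[fid] = lnc[0]
    return out


class TestAssignGenes:
    GENES = [
        GeneModel("C1", "coding", "chr1", 1000, 2000, "+"),
        GeneModel("L1", "lncRNA", "chr1", 1500, 2500, "+"),
        GeneModel("L2", "lncRNA", "chr1", 5000, 6000, "+"),
    ]

    def test_probe_in_single_lncrna(self):
        pmap = assign_genes([aln(start=5100, end=5160)], self.GENES)
        assert pmap.assignments == {"p": "L2"}

    def test_coding_priority_over_lncrna(self):
        pmap = assign_genes([aln(start=1600, end=1660)], self.GENES)
        assert pmap.assignments == {"p": "C1"}
        assert pmap.provenance["p"]["coding_priority_applied"] is True

    def test_two_coding_genes_dropped_as_ambiguous(self):
        genes = self.GENES + [GeneModel("C2", "coding", "chr1", 1500, 2600, "+")]
        pmap = assign_genes([aln(start=1600, end=1660)], genes)
        assert pmap.assignments == {}
        assert pmap.provenance["p"]["drop_reason"] == "ambiguous"
        assert pmap.provenance["p"]["n_candidates"] == 3

    def test_strand_must_match_unless_ignored(self):
        rec = aln(start=1100, end=1160, strand="-")
        assert assign_genes([rec], self.GENES).assignments == {}
        assert assign_genes([rec], self.GENES, ignore_strand=True).assignments \
            == {"p": "C1"}

    def test_multimapping_feature_dropped_entirely(self):
        records = [aln(start=1100, end=1160), aln(start=5100, end=5160)]
        pmap = assign_genes(records, self.GENES)
        assert pmap.assignments == {}
        assert pmap.provenance["p"]["drop_reason"] == "multimapping"

    def test_agrees_with_bruteforce_interval_scan(self):
        rng = random.Random(4)
        genes = []
        for i in range(40):
            start = rng.randrange(0, 50_000, 100)
            genes.append(
                GeneModel(f"g{i}", rng.choice(["coding", "lncRNA"]),
                          rng.choice(["chr1", "chr2"]), start,
                          start + rng.randrange(500, 3000, 100),
                          rng.choice("+-"))
            )
        features = []
        for i in range(200):
            start = rng.randrange(0, 52_000)
            features.append(
                aln(f"p{i}", chrom=rng.choice(["chr1", "chr2"]), start=start,
                    end=start + 60, strand=rng.choice("+-"))
            )
        got = assign_genes(features, genes).assignments
        assert got == brute_force_assign(features, genes)


class TestFixturePipeline:
    def test_fixture_truth_recovered_exactly(self, tmp_path):
        _, _, truth = generate_probe_fixture(SynthConfig(seed=0), tmp_path)
        alignments = read_psl(tmp_path / "probes.psl")
        genes = read_gtf(tmp_path / "genes.gtf")
        pmap = reannotate(alignments, genes)
        assert pmap.assignments == truth.probe_truth_map
        for feature in truth.probe_drop_reasons:
            assert feature not in pmap.assignments

    def test_gtf_coordinates_converted_to_half_open(self, tmp_path):
        generate_probe_fixture(SynthConfig(seed=0), tmp_path)
        genes = {g.gene_id: g for g in read_gtf(tmp_path / "genes.gtf")}
        assert (genes["C1"].start, genes["C1"].end) == (1000, 2000)
        assert genes["L1"].biotype == "lncRNA"
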