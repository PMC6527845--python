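"""Sentence segmentation, dictionary matching and abstract annotation."""

import random
import re

import pytest

from cmapminer.corpus import (
    Abstract,
    Lexicon,
    annotate_abstract,
    match_terms,
    read_corpus,
    read_lexicons,
    segment_sentences,
)

# Hand-segmented fixture: 3 sentences; "vs." and "et al." must not split.
HAND_SEGMENTED = (
    "Smith et al. compared tumor vs. normal tissue in 40 patients. "
    "EGFR expression was higher in tumors. "
    "The difference was significant (P < 0.01)."
)


class TestSegmentation:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("", 0),
            ("   ", 0),
            ("EGFR is overexpressed in HNC. Cetuximab targets EGFR.", 2),
            (HAND_SEGMENTED, 3),
            ("One sentence without terminal period", 1),
            ("Values were 3.5 and 4.2 respectively. Next sentence here.", 2),
        ],
    )
    def test_sentence_counts(self, text, expected):
        assert len(segment_sentences(text)) == expected

    def test_reconstruction_modulo_whitespace(self):
        sentences = segment_sentences(HAND_SEGMENTED)
        joined = re.sub(r"\s+", "", " ".join(sentences))
        assert joined == re.sub(r"\s+", "", HAND_SEGMENTED)

    def test_abbreviations_protected(self):
        text = "We used e.g. EGFR and TP53. Results follow."
        assert len(segment_sentences(text)) == 2

    def test_single_initials_protected(self):
        text = "The method of J. Smith was used. It worked."
        assert len(segment_sentences(text)) == 2

    def test_extra_abbreviations_extend_the_list(self):
        text = "Samples were from cohort Xy. Next sentence."
        assert len(segment_sentences(text)) == 2
        assert len(segment_sentences(text, extra_abbreviations=["Xy."])) == 1


class TestMatchTerms:
    def test_no_terms(self, gene_lexicon):
        assert match_terms("nothing relevant here", gene_lexicon) == []

    def test_case_insensitive_two_hits(self):
        lex = Lexicon("gene", {"G:EGFR": {"EGFR"}})
        hits = match_terms("egfr and EGFR", lex)
        assert len(hits) == 2
        assert all(h.canonical_id == "G:EGFR" for h in hits)

    def test_longest_match_wins(self, gene_lexicon):
        hits = match_terms("TP53BP1 studied", gene_lexicon)
        assert [h.canonical_id for h in hits] == ["G:TP53BP1"]

    def test_hyphen_is_a_boundary(self, gene_lexicon):
        hits = match_terms("EGFR-positive tumors", gene_lexicon)
        assert [h.canonical_id for h in hits] == ["G:EGFR"]

    def test_no_substring_matches(self, gene_lexicon):
        assert match_terms("EGFRX and xEGFR", gene_lexicon) == []

    def test_span_slice_equals_matched_text(self, gene_lexicon):
        sentence = "Both EGFR-positive and p53-null lines grew."
        for h in match_terms(sentence, gene_lexicon):
            start, end = h.char_span
            assert sentence[start:end] == h.matched_text

    def test_ambiguous_synonym_yields_one_hit_per_id(self):
        lex = Lexicon("gene", {"G:A": {"KRAS"}, "G:B": {"KRAS"}})
        hits = match_terms("KRAS mutation", lex)
        assert sorted(h.canonical_id for h in hits) == ["G:A", "G:B"]

    def test_agrees_with_bruteforce_regex_oracle(self, gene_lexicon):
        """Greedy longest-match equals a per-synonym regex scan with
        longest-at-position selection, on random sentences."""
        rng = random.Random(0)
        words = ["EGFR", "TP53", "TP53BP1", "p53", "tumor", "the", "xEGFR"]
        synonyms = {
            s: cid
            for cid, syns in gene_lexicon.entries.items()
            for s in syns
        }
        for _ in range(50):
            sentence = " ".join(rng.choices(words, k=rng.randint(1, 12)))
            # oracle: all per-synonym matches, then greedy left-to-right
            # longest-first selection
            candidates = []
            for syn, cid in synonyms.items():
                for m in re.finditer(
                    rf"(?<![A-Za-z0-9]){re.escape(syn)}(?![A-Za-z0-9])",
                    sentence,
                    re.IGNORECASE,
                ):
                    candidates.append((m.start(), -len(m.group(0)), cid))
            candidates.sort()
            chosen, pos = [], -1
            for start, neglen, cid in candidates:
                if start > pos:
                    chosen.append((start, cid))
                    pos = start - neglen - 1
            got = [
                (h.char_span[0], h.canonical_id)
                for h in match_terms(sentence, gene_lexicon)
            ]
            assert sorted(got) == sorted(chosen)


class TestAnnotateAbstract:
    def test_zero_hits(self, disease_lexicon, gene_lexicon, drug_lexicon):
        a = Abstract("A1", "Nothing relevant was found. Testing continued.")
        ann = annotate_abstract(a, disease_lexicon, gene_lexicon, drug_lexicon)
        assert (ann.n_c, ann.n_hnc, ann.n_gene, ann.n_drug) == (0, 0, 0, 0)
        assert (ann.flag_gene, ann.flag_drug, ann.flag_hnc) == (0, 0, 0)

    def test_single_cooccurrence_sentence(
        self, disease_lexicon, gene_lexicon, drug_lexicon
    ):
        a = Abstract("A1", "EGFR is overexpressed in oral cancer.")
        ann = annotate_abstract(a, disease_lexicon, gene_lexicon, drug_lexicon)
        assert (ann.n_c, ann.n_hnc, ann.n_gene) == (1, 0, 0)
        assert (ann.flag_gene, ann.flag_hnc) == (1, 1)

    def test_four_sentence_hand_count(
        self, disease_lexicon, gene_lexicon, drug_lexicon
    ):
        # 1 co-occurrence + 2 disease-only + 1 gene-only
        text = (
            "EGFR drives oral cancer progression. "
            "Head and neck cancer is common. "
            "Oral cancer incidence is rising. "
            "TP53 was sequenced in all samples."
        )
        ann = annotate_abstract(
            Abstract("A1", text), disease_lexicon, gene_lexicon, drug_lexicon
        )
        assert (ann.n_c, ann.n_hnc, ann.n_gene) == (1, 2, 1)

    def test_title_is_sentence_zero(
        self, disease_lexicon, gene_lexicon, drug_lexicon
    ):
        a = Abstract("A1", "TP53 was profiled.", title="EGFR in oral cancer")
        ann = annotate_abstract(a, disease_lexicon, gene_lexicon, drug_lexicon)
        assert ann.n_c == 1  # the title co-mentions disease and gene
        assert min(h.sentence_index for h in ann.hits) == 0

    def test_sentence_contributes_to_at_most_one_disease_count(
        self, disease_lexicon, gene_lexicon, drug_lexicon
    ):
        """Conservation: n_c + n_hnc never exceeds the sentence count."""
        texts = [
            "EGFR and cetuximab in oral cancer. HNSCC is aggressive.",
            "Oral cancer. EGFR. cetuximab.",
            "HNSCC with EGFR. HNSCC alone here.",
        ]
        for text in texts:
            ann = annotate_abstract(
                Abstract("A", text), disease_lexicon, gene_lexicon, drug_lexicon
            )
            assert ann.n_c + ann.n_hnc <= ann.n_sentences

    def test_drug_hit_does_not_block_cooccurrence(
        self, disease_lexicon, gene_lexicon, drug_lexicon
    ):
        text = "Cetuximab targets EGFR in oral cancer."
        ann = annotate_abstract(
            Abstract("A", text), disease_lexicon, gene_lexicon, drug_lexicon
        )
        assert ann.n_c == 1 and ann.n_gene == 0 and ann.n_drug == 0

    def test_gene_and_drug_only_sentence_counts_in_both(
        self, disease_lexicon, gene_lexicon, drug_lexicon
    ):
        ann = annotate_abstract(
            Abstract("A", "Cetuximab inhibits EGFR."),
            disease_lexicon, gene_lexicon, drug_lexicon,
        )
        assert (ann.n_gene, ann.n_drug, ann.n_c) == (1, 1, 0)

    def test_flag_hnc_toggle(self, disease_lexicon, gene_lexicon, drug_lexicon):
        a = Abstract("A", "Oral cancer was studied. TP53 was mutated.")
        strict = annotate_abstract(
            a, disease_lexicon, gene_lexicon, drug_lexicon,
            flag_hnc_from_any_disease=False,
        )
        assert strict.flag_hnc == 1  # disease-only sentence still present

    def test_determinism_under_lexicon_entry_order(
        self, disease_lexicon, drug_lexicon
    ):
        entries = {"G:EGFR": {"EGFR"}, "G:TP53": {"TP53", "p53"},
                   "G:TP53BP1": {"TP53BP1"}}
        a = Abstract("A", "TP53BP1 and EGFR in oral cancer. p53 too.")
        anns = []
        for order in (list(entries), list(reversed(list(entries)))):
            lex = Lexicon("gene", {k: entries[k] for k in order})
            anns.append(
                annotate_abstract(a, disease_lexicon, lex, drug_lexicon)
            )
        a0, a1 = anns
        assert (a0.n_c, a0.n_hnc, a0.n_gene) == (a1.n_c, a1.n_hnc, a1.n_gene)
        assert sorted((h.sentence_index, h.canonical_id) for h in a0.hits) == \
            sorted((h.sentence_index, h.canonical_id) for h in a1.hits)


class TestIO:
    def test_corpus_and_lexicon_roundtrip(self, tmp_path):
        corpus = tmp_path / "corpus.tsv"
        corpus.write_text(
            "abstract_id\ttext\nA1\tEGFR in oral cancer.\nA2\tNothing here.\n"
        )
        abstracts = read_corpus(corpus)
        assert [a.abstract_id for a in abstracts] == ["A1", "A2"]
        lex_file = tmp_path / "lex.tsv"
        lex_file.write_text(
            "canonical_id\tcategory\tsynonym\n"
            "DIS:HNC\tdisease\toral cancer\n"
            "G:EGFR\tgene\tEGFR\n"
            "G:EGFR\tgene\tErbB-1\n"
        )
        lexicons = read_lexicons(lex_file)
        assert set(lexicons) == {"disease", "gene"}
        assert lexicons["gene"].entries["G:EGFR"] == {"EGFR", "ErbB-1"}

    def test_empty_synonym_rejected(self):
        with pytest.raises(ValueError):
            Lexicon("gene", {"G:X": {""}})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            Lexicon("protein", {"X": {"x"}})
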