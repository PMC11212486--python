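"""Dataset IO, validation, curation and split contracts."""

import numpy as np
import pytest

from cppmine import data_io
from cppmine.data_io import (CurationReport, FastaParseError, LabeledDataset,
                             Peptide, greedy_redundancy_filter, kfold_split,
                             length_filter, make_imbalanced_split,
                             pairwise_identity, read_fasta, validate_natural,
                             write_fasta)


def make_ds(seqs, labels=None, prefix="p"):
    return LabeledDataset(
        peptides=[Peptide(f"{prefix}{i}", s) for i, s in enumerate(seqs)],
        labels=list(labels) if labels is not None else [])


class TestFasta:
    def test_round_trip_identity(self, tmp_path):
        ds = make_ds(["ACDEF", "GHIKLMNPQR", "WY"])
        path = tmp_path / "pep.fasta"
        write_fasta(ds, path)
        back = read_fasta(path)
        assert back.ids == ds.ids
        assert back.sequences == ds.sequences

    def test_lowercase_normalized(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">p1\nacd\n")
        assert read_fasta(path).sequences == ["ACD"]

    def test_wrapped_lines_concatenated(self, tmp_path):
        path = tmp_path / "wrap.fasta"
        path.write_text(">p1 some description\nACD\nEFG\n")
        ds = read_fasta(path)
        assert ds.ids == ["p1"]          # id is header up to whitespace
        assert ds.sequences == ["ACDEFG"]

    def test_header_only_record_raises(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">p1\n>p2\nACD\n")
        with pytest.raises(FastaParseError, match="p1"):
            read_fasta(path)

    def test_empty_file_warns_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            ds = read_fasta(path)
        assert len(ds) == 0

    def test_not_fasta_raises(self, tmp_path):
        path = tmp_path / "notfasta.txt"
        path.write_text("ACDEF\n")
        with pytest.raises(FastaParseError):
            read_fasta(path)


class TestTable:
    def test_csv_round_trip_with_labels(self, tmp_path):
        ds = make_ds(["ACD", "EFG"], labels=[1, 0])
        path = tmp_path / "t.csv"
        data_io.write_table(ds, path)
        back = data_io.read_table(path)
        assert back.sequences == ds.sequences
        assert back.labels == [1, 0]


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        LabeledDataset(peptides=[Peptide("a", "ACD"), Peptide("a", "EFG")])


@pytest.mark.parametrize("seq,expected", [
    ("ACDEFGHIKLMNPQRSTVWY", True),   # the full natural alphabet
    ("ACXB", False),                   # X and B are non-natural
    ("", False),                       # empty is invalid
    ("acd", False),                    # validation is on normalized uppercase
])
def test_validate_natural(seq, expected):
    assert validate_natural(seq) is expected


class TestLengthFilter:
    def test_threshold_50_boundary(self):
        ds = make_ds(["A" * 10, "C" * 50, "D" * 51])
        kept = length_filter(ds, max_len=50)
        assert [p.length for p in kept] == [10, 50]

    def test_identity_when_all_short(self):
        ds = make_ds(["ACD", "EF"])
        assert length_filter(ds, 50).sequences == ds.sequences

    def test_max_len_zero_rejected(self):
        with pytest.raises(ValueError):
            length_filter(make_ds(["A"]), max_len=0)


class TestIdentity:
    def test_exact_match(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 1.0

    def test_ninety_percent(self):
        # 9 of 10 alignment columns match; shorter length 10
        assert pairwise_identity("AAAAAAAAAA", "AAAAAAAAAC") == pytest.approx(0.9)

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_length_normalized_by_shorter(self):
        # "ACD" aligns fully inside "ACDEF": 3 matches / 3
        assert pairwise_identity("ACD", "ACDEF") == 1.0

    def test_symmetry(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), size=rng.integers(1, 12)))
            b = "".join(rng.choice(list(aas), size=rng.integers(1, 12)))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a))


class TestRedundancyFilter:
    def test_exact_duplicates_collapse(self):
        ds = make_ds(["ACDEF", "ACDEF"])
        out = greedy_redundancy_filter(ds)
        assert len(out) == 1

    def test_ninety_percent_pair_collapses_at_80(self):
        ds = make_ds(["AAAAAAAAAA", "AAAAAAAAAC"])
        out = greedy_redundancy_filter(ds, 0.80)
        assert len(out) == 1

    def test_dissimilar_kept(self):
        ds = make_ds(["AAAA", "CCCC"])
        assert len(greedy_redundancy_filter(ds, 0.80)) == 2

    def test_report_counts(self):
        report = CurationReport(n_input=3)
        ds = make_ds(["ACDEF", "ACDEF", "WWWW"])
        out = greedy_redundancy_filter(ds, 0.80, report)
        assert report.n_removed_redundant == 1
        assert report.n_output == len(out) == 2

    def test_against_all_pairs_oracle(self, rng):
        """No retained pair reaches the threshold, and every removed sequence
        is explained by a retained one at/above it (greedy cover property)."""
        aas = "ACDW"  # small alphabet forces collisions
        seqs = list({"".join(rng.choice(list(aas), size=rng.integers(4, 9)))
                     for _ in range(30)})
        ds = make_ds(seqs)
        out = greedy_redundancy_filter(ds, 0.75)
        kept = out.sequences
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert pairwise_identity(a, b) < 0.75
        removed = set(seqs) - set(kept)
        for r in removed:
            assert any(pairwise_identity(r, k) >= 0.75 for k in kept)


class TestImbalancedSplit:
    def test_exact_ratio_arithmetic(self):
        pos = make_ds(["R" * 8] * 1, prefix="pos")
        pos = LabeledDataset(peptides=[Peptide(f"pos{i}", "RR" + "A" * i)
                                       for i in range(10)])
        pool = LabeledDataset(peptides=[Peptide(f"n{i}", "GGGG")
                                        for i in range(5000)])
        out = make_imbalanced_split(pos, pool, ratio=100, seed=0)
        assert len(out) == 1010
        assert out.n_positive() == 10
        assert out.n_negative() == 1000

    def test_deterministic_per_seed(self):
        pos = LabeledDataset(peptides=[Peptide("p0", "RRA")])
        pool = LabeledDataset(peptides=[Peptide(f"n{i}", "GGG")
                                        for i in range(50)])
        a = make_imbalanced_split(pos, pool, 10, seed=7)
        b = make_imbalanced_split(pos, pool, 10, seed=7)
        c = make_imbalanced_split(pos, pool, 10, seed=8)
        assert a.ids == b.ids
        assert a.ids != c.ids

    def test_insufficient_pool_error_names_counts(self):
        pos = LabeledDataset(peptides=[Peptide("p0", "RRA")])
        pool = LabeledDataset(peptides=[Peptide("n0", "GGG")])
        with pytest.raises(ValueError, match="need 10, have 1"):
            make_imbalanced_split(pos, pool, 10, seed=0)


class TestKFold:
    @staticmethod
    def balanced_ds(n):
        peptides = [Peptide(f"x{i}", "RRAA" if i % 2 else "GGGG")
                    for i in range(n)]
        return LabeledDataset(peptides=peptides,
                              labels=[i % 2 for i in range(n)])

    def test_fold_sizes_924(self):
        tags = kfold_split(self.balanced_ds(924), k=10, seed=0)
        sizes = {t: tags.count(t) for t in set(tags)}
        assert set(sizes.values()) <= {92, 93}
        assert sum(sizes.values()) == 924

    def test_stratification_within_one(self):
        ds = self.balanced_ds(100)
        tags = kfold_split(ds, k=10, seed=0)
        for fold in set(tags):
            labels = [ds.labels[i] for i, t in enumerate(tags) if t == fold]
            assert abs(sum(labels) - len(labels) / 2) <= 1

    def test_deterministic(self):
        ds = self.balanced_ds(60)
        assert kfold_split(ds, 5, seed=3) == kfold_split(ds, 5, seed=3)

    def test_k_larger_than_dataset_errors(self):
        with pytest.raises(ValueError):
            kfold_split(self.balanced_ds(4), k=10, seed=0)


def test_curation_order_insensitive(rng):
    seqs = ["ACDEF", "A" * 60, "ACXDE", "WYWYWY", "RRKKWW"]
    ds_fwd = make_ds(seqs)
    ds_rev = make_ds(list(reversed(seqs)), prefix="q")
    out_fwd = data_io.natural_filter(length_filter(ds_fwd, 50))
    out_rev = data_io.natural_filter(length_filter(ds_rev, 50))
    assert set(out_fwd.sequences) == set(out_rev.sequences)


def test_drop_conflicting_labels():
    pos = make_ds(["RRKK", "WWWW"], prefix="p")
    neg = make_ds(["WWWW", "GGGG"], prefix="n")
    pos2, neg2 = data_io.drop_conflicting(pos, neg)
    assert pos2.sequences == ["RRKK"]
    assert neg2.sequences == ["GGGG"]
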