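"""Augmentation operators: substitutions, indels, decoration, balancing."""

import numpy as np
import pytest

from ednacnn.augment import (
    TELEO_FORWARD_PRIMER,
    TELEO_REVERSE_PRIMER,
    AugmentConfig,
    balance_oversample,
    decorate,
    indel,
    make_epoch_batch,
    substitute,
)
from ednacnn.refdb import ReferenceDB, ReferenceRecord
from ednacnn.seqcodec import encode, shape_to_width

IUPAC = set("ACGTRYSWKMBDHVN")


class TestSubstitute:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        assert substitute("ACGTN", 0.0, rng) == "ACGTN"

    def test_rate_one_changes_every_canonical_base(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 25
        out = substitute(seq, 1.0, rng)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    @pytest.mark.parametrize("rate", [0.05, 0.02])
    def test_empirical_rate_within_three_binomial_se(self, rate):
        rng = np.random.default_rng(12345)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        n_draws, length = 10_000, len(seq)
        changed = sum(
            sum(a != b for a, b in zip(seq, substitute(seq, rate, rng)))
            for _ in range(n_draws)
        )
        total = n_draws * length
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(changed / total - rate) < 3 * se

    def test_ambiguity_codes_become_canonical_when_hit(self):
        rng = np.random.default_rng(1)
        out = substitute("N" * 100, 1.0, rng)
        assert set(out) <= set("ACGT")

    def test_output_stays_iupac(self):
        rng = np.random.default_rng(2)
        out = substitute("ACGTNRYSWKM" * 5, 0.5, rng)
        assert set(out) <= IUPAC


class TestIndel:
    def test_zero_bounds_identity(self):
        rng = np.random.default_rng(0)
        assert indel("ACGTACGT", 0, 0, rng) == "ACGTACGT"

    def test_length_bounds_and_attainment(self):
        rng = np.random.default_rng(7)
        seq = "ACGT" * 15
        deltas = {len(indel(seq, 2, 2, rng)) - len(seq) for _ in range(3000)}
        assert deltas == {-2, -1, 0, 1, 2}

    def test_deletions_capped_on_short_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = indel("AC", 0, 5, rng)
            assert len(out) >= 1


class TestDecorate:
    def test_structure_and_length_arithmetic(self):
        amplicon = "A" * 60
        out = decorate(amplicon, TELEO_FORWARD_PRIMER, TELEO_REVERSE_PRIMER, 10)
        # 10 + 17 + 60 + 20 + 10
        assert len(out) == 10 + len(TELEO_FORWARD_PRIMER) + 60 + len(TELEO_REVERSE_PRIMER) + 10
        assert out.startswith("N" * 10)
        assert out.endswith("N" * 10)
        assert TELEO_FORWARD_PRIMER + amplicon in out

    def test_reverse_primer_appears_reverse_complemented(self):
        out = decorate("AAAA", "GG", "CAT", 0)
        assert out == "GG" + "AAAA" + "ATG"

    def test_empty_decoration_is_identity(self):
        assert decorate("ACGT", "", "", 0) == "ACGT"


class TestBalanceOversample:
    @staticmethod
    def _db(counts):
        recs = []
        for sp, n in counts.items():
            for i in range(n):
                recs.append(ReferenceRecord(f"{sp}{i}", sp, "ACGT" + "ACGT"[i % 4]))
        return ReferenceDB(recs)

    def test_equalizes_to_max_count(self):
        out = balance_oversample(self._db({"A": 3, "B": 1}), np.random.default_rng(0))
        per = {}
        for r in out.records:
            per[r.species] = per.get(r.species, 0) + r.multiplicity
        assert per == {"A": 3, "B": 3}
        assert out.total_copies() == 2 * 3

    def test_balanced_db_unchanged_counts(self):
        out = balance_oversample(self._db({"A": 2, "B": 2}), np.random.default_rng(0))
        assert out.total_copies() == 4


class TestEpochBatch:
    @staticmethod
    def _db():
        return ReferenceDB(
            [ReferenceRecord("a", "A", "ACGTACGTAC"), ReferenceRecord("b", "B", "TTTTACGTAA")]
        )

    def test_noise_free_batch_equals_encoded_references(self):
        cfg = AugmentConfig.none(target_width=12)
        X, y = make_epoch_batch(self._db(), cfg, np.random.default_rng(0))
        assert X.shape == (2, 12, 4)
        np.testing.assert_allclose(X[0], shape_to_width(encode("ACGTACGTAC"), 12))
        assert list(y) == [0, 1]

    def test_reverse_complements_double_the_batch(self):
        cfg = AugmentConfig.none(add_reverse_complements=True, target_width=12)
        X, y = make_epoch_batch(self._db(), cfg, np.random.default_rng(0))
        assert X.shape[0] == 4
        assert list(y) == [0, 0, 1, 1]

    def test_fresh_randomness_each_epoch(self):
        cfg = AugmentConfig.training(target_width=20)
        rng = np.random.default_rng(0)
        X1, _ = make_epoch_batch(self._db(), cfg, rng)
        X2, _ = make_epoch_batch(self._db(), cfg, rng)
        assert not np.allclose(X1, X2)

    def test_shapes_uniform_at_target_width(self):
        cfg = AugmentConfig.training(decorate=True, target_width=150)
        X, _ = make_epoch_batch(self._db(), cfg, np.random.default_rng(0))
        assert X.shape[1:] == (150, 4)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = AugmentConfig.evaluation(decorate=True)
        cfg.to_yaml(tmp_path / "aug.yaml")
        back = AugmentConfig.from_yaml(tmp_path / "aug.yaml")
        assert back == cfg

    def test_evaluation_mode_settings(self):
        cfg = AugmentConfig.evaluation()
        assert cfg.sub_rate == 0.02
        assert cfg.max_insertions == cfg.max_deletions == 1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(sub_rate=1.5)
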