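"""Training-time sequence augmentation.

Reference databases for short barcodes are small and unbalanced, and raw
reads carry tags, primers and sequencing noise that the references lack.
Training therefore draws, every epoch, a freshly perturbed copy of each
reference sequence: class balancing by oversampling, point substitutions
(5% per position during training, 2% or none during evaluation), zero to
two random insertions and deletions, optional raw-read-style decoration
(N-blocks standing in for tag + attachment bases, plus the PCR primers),
and optional reverse complements so both strands are recognised.

A "mutation" always changes the base: substitutions draw uniformly from
the three bases different from the original (ambiguity codes are replaced
by a uniform draw over A/C/G/T).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from .refdb import ReferenceDB, ReferenceRecord
from .seqcodec import encode, reverse_complement, shape_to_width

__all__ = [
    "TELEO_FORWARD_PRIMER",
    "TELEO_REVERSE_PRIMER",
    "AugmentConfig",
    "substitute",
    "indel",
    "decorate",
    "balance_oversample",
    "make_epoch_batch",
]

#: 12S "teleo" primer pair targeting teleost fishes (~60 bp amplicon).
TELEO_FORWARD_PRIMER = "ACACCGCCCGTCACTCT"
TELEO_REVERSE_PRIMER = "CTTCCGGTACACTTACCATG"

_CANON = "ACGT"
_OTHERS = {b: _CANON.replace(b, "") for b in _CANON}


@dataclass
class AugmentConfig:
    """Parameters of the per-epoch augmentation.

    Defaults are the training-mode settings: 5% substitution rate, up to
    two insertions and two deletions, 10-bp N blocks standing in for the
    8-bp tag plus 2 attachment bases, and a 150-position model width.
    """

    sub_rate: float = 0.05
    max_insertions: int = 2
    max_deletions: int = 2
    n_prefix_len: int = 10
    decorate: bool = False
    add_reverse_complements: bool = False
    target_width: int = 150
    forward_primer: str = TELEO_FORWARD_PRIMER
    reverse_primer: str = TELEO_REVERSE_PRIMER

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError(f"sub_rate must be in [0, 1], got {self.sub_rate}")
        if self.max_insertions < 0 or self.max_deletions < 0:
            raise ValueError("indel bounds must be >= 0")
        if self.n_prefix_len < 0:
            raise ValueError("n_prefix_len must be >= 0")
        if self.target_width < 1:
            raise ValueError("target_width must be >= 1")

    @classmethod
    def training(cls, **overrides) -> "AugmentConfig":
        """Training-mode augmentation (5% substitutions, 0-2 indels)."""
        return cls(**overrides)

    @classmethod
    def evaluation(cls, **overrides) -> "AugmentConfig":
        """Evaluation-mode augmentation: 2% noise, single indels.

        PCR and sequencing are expected to be cleaner than the training
        noise level, so evaluation perturbs less.
        """
        defaults = dict(sub_rate=0.02, max_insertions=1, max_deletions=1)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def none(cls, **overrides) -> "AugmentConfig":
        """No-op augmentation (identity batches)."""
        defaults = dict(sub_rate=0.0, max_insertions=0, max_deletions=0)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "AugmentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def substitute(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    """Mutate each position independently with probability ``sub_rate``.

    A mutated canonical base becomes one of the three *other* bases
    (uniformly), so the observed change frequency equals ``sub_rate``;
    a mutated ambiguity code becomes a uniform draw over A/C/G/T.
    Length-preserving.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError(f"sub_rate must be in [0, 1], got {sub_rate}")
    if sub_rate == 0.0 or not seq:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < sub_rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        c = chars[i].upper()
        if c in _OTHERS:
            chars[i] = _OTHERS[c][rng.integers(3)]
        else:
            chars[i] = _CANON[rng.integers(4)]
    return "".join(chars)


def indel(
    seq: str,
    max_insertions: int,
    max_deletions: int,
    rng: np.random.Generator,
) -> str:
    """Apply ``k_ins ~ U{0..max_insertions}`` insertions then ``k_del``
    deletions at uniform positions.

    Inserted bases are uniform over A/C/G/T.  Deletions are capped at
    ``len(seq) - 1`` so the result is never empty.  Output length is
    ``len(seq) + k_ins - k_del``.
    """
    if max_insertions < 0 or max_deletions < 0:
        raise ValueError("indel bounds must be >= 0")
    k_ins = int(rng.integers(0, max_insertions + 1))
    k_del = int(rng.integers(0, max_deletions + 1))
    k_del = min(k_del, len(seq) - 1)
    chars = list(seq)
    for _ in range(k_ins):
        pos = int(rng.integers(0, len(chars) + 1))
        chars.insert(pos, _CANON[rng.integers(4)])
    for _ in range(k_del):
        pos = int(rng.integers(0, len(chars)))
        del chars[pos]
    return "".join(chars)


def decorate(
    seq: str,
    forward_primer: str,
    reverse_primer: str,
    n_prefix_len: int = 10,
) -> str:
    """Dress a bare amplicon the way it appears in a forward raw read.

    Returns ``N*n + forward_primer + seq + revcomp(reverse_primer) + N*n``:
    the N blocks stand in for the 8-bp tag plus up to 2 attachment bases on
    each side, and the reverse primer appears as its reverse complement
    (its orientation in a forward read).
    """
    block = "N" * n_prefix_len
    tail = reverse_complement(reverse_primer) if reverse_primer else ""
    return block + forward_primer + seq + tail + block


def balance_oversample(
    db: ReferenceDB, rng: np.random.Generator
) -> ReferenceDB:
    """Oversample under-represented species to the maximum per-species count.

    Every species ends with the same number of sequence copies (records
    counted with multiplicity), drawn with replacement from its own
    records.  Deterministic given the generator state.
    """
    by_species: dict[str, list[ReferenceRecord]] = {}
    for r in db.records:
        by_species.setdefault(r.species, []).extend([r] * r.multiplicity)
    if not by_species:
        return ReferenceDB([])
    target = max(len(v) for v in by_species.values())
    out: list[ReferenceRecord] = []
    for sp in sorted(by_species):
        pool = by_species[sp]
        picks = list(pool)
        extra = target - len(pool)
        if extra > 0:
            idx = rng.integers(0, len(pool), size=extra)
            picks.extend(pool[i] for i in idx)
        for j, r in enumerate(picks):
            out.append(replace(r, record_id=f"{r.record_id}.bal{j}", multiplicity=1))
    return ReferenceDB(out)


def make_epoch_batch(
    db: ReferenceDB,
    config: AugmentConfig,
    rng: np.random.Generator,
    label_index: dict[str, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one epoch's worth of freshly augmented, encoded training pairs.

    Per record (and per collapsed duplicate): optional decoration, then
    indels, then substitutions, then optional reverse-complement
    duplication, then encoding and shaping to ``config.target_width``.
    Returns ``(X, y)`` with ``X`` of shape ``(N, target_width, 4)`` and
    integer class labels ``y``.
    """
    idx = label_index if label_index is not None else db.label_index
    seqs: list[str] = []
    labels: list[int] = []
    for rec in db.records:
        for _ in range(rec.multiplicity):
            s = rec.sequence
            if config.decorate:
                s = decorate(
                    s,
                    config.forward_primer,
                    config.reverse_primer,
                    config.n_prefix_len,
                )
            s = indel(s, config.max_insertions, config.max_deletions, rng)
            s = substitute(s, config.sub_rate, rng)
            seqs.append(s)
            labels.append(idx[rec.species])
            if config.add_reverse_complements:
                seqs.append(reverse_complement(s))
                labels.append(idx[rec.species])
    X = np.stack(
        [shape_to_width(encode(s), config.target_width) for s in seqs]
    ) if seqs else np.zeros((0, config.target_width, 4))
    return X, np.asarray(labels, dtype=int)
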