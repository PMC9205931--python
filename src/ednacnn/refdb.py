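"""Reference barcode database and tag manifest I/O.

A :class:`ReferenceDB` holds species-labelled amplicon sequences (the
training universe of the classifier) together with a dense, stable
species -> class-integer index.  A :class:`TagManifest` maps each PCR
replicate (sample) to its 8-bp demultiplexing tags, PCR primers and
filter/river metadata, in an ngsfilter-style tab-separated dialect.

Split sampling: species with at least ``min_unique`` distinct sequences
can contribute one held-out unique sequence each, giving a train/hold-out
partition that covers every eligible species on both sides.
"""

from __future__ import annotations

import gzip
import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from Bio import SeqIO

from .seqcodec import encode

__all__ = [
    "ReferenceRecord",
    "ReferenceDB",
    "TagEntry",
    "TagManifest",
    "read_reference_fasta",
    "write_reference_fasta",
    "eligible_species_for_split",
    "split_train_holdout",
    "read_tag_manifest",
    "write_tag_manifest",
    "save_label_index",
    "load_label_index",
]


@dataclass(frozen=True)
class ReferenceRecord:
    """One barcode record: a primer-free amplicon with its species label.

    ``multiplicity`` counts collapsed exact duplicates of the same
    (sequence, species) pair.
    """

    record_id: str
    species: str
    sequence: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        if not self.species:
            raise ValueError(f"record {self.record_id!r}: empty species label")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


class ReferenceDB:
    """Labelled barcode records plus a species <-> class-integer bijection.

    The label index assigns dense integers ``0..C-1`` to the distinct
    species labels in lexicographic order, which makes it stable under
    serialization and independent of record order.
    """

    def __init__(self, records: Iterable[ReferenceRecord]):
        self.records: list[ReferenceRecord] = list(records)
        species = sorted({r.species for r in self.records})
        self.label_index: dict[str, int] = {sp: i for i, sp in enumerate(species)}

    @property
    def species(self) -> list[str]:
        """Species labels in class-integer order."""
        return sorted(self.label_index, key=self.label_index.get)

    @property
    def n_classes(self) -> int:
        return len(self.label_index)

    def __len__(self) -> int:
        return len(self.records)

    def total_copies(self) -> int:
        """Number of records counting collapsed duplicates."""
        return sum(r.multiplicity for r in self.records)

    def sequences_by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for r in self.records:
            out[r.species].append(r.sequence)
        return dict(out)

    def unique_sequence_counts(self) -> dict[str, int]:
        """Distinct sequence strings per species."""
        return {sp: len(set(seqs)) for sp, seqs in self.sequences_by_species().items()}

    def filter_species(self, keep: set[str]) -> "ReferenceDB":
        return ReferenceDB([r for r in self.records if r.species in keep])


def _default_label_parser(record_id: str, description: str) -> str:
    """Default species label: full FASTA header after the first whitespace."""
    parts = description.split(None, 1)
    if len(parts) < 2 or not parts[1].strip():
        raise ValueError("no species label after the record id")
    return parts[1].strip()


def read_reference_fasta(
    path: str | Path,
    label_parser: Callable[[str, str], str] | None = None,
) -> ReferenceDB:
    """Read a reference FASTA into a :class:`ReferenceDB`.

    ``label_parser(record_id, description)`` extracts the species label from
    each header; the default takes everything after the first whitespace.
    Exact duplicate (sequence, species) pairs are collapsed into a single
    record with ``multiplicity`` retained.
    """
    parser = label_parser or _default_label_parser
    path = Path(path)
    merged: dict[tuple[str, str], ReferenceRecord] = {}
    n_entries = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        n_entries += 1
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path.name}, entry {i} ({rec.id}): empty sequence")
        try:
            species = parser(rec.id, rec.description)
        except ValueError as exc:
            raise ValueError(f"{path.name}, entry {i} ({rec.id}): {exc}") from None
        encode(seq)  # validates the IUPAC alphabet, reports the position
        key = (seq, species)
        if key in merged:
            old = merged[key]
            merged[key] = replace(old, multiplicity=old.multiplicity + 1)
        else:
            merged[key] = ReferenceRecord(rec.id, species, seq)
    if n_entries == 0:
        raise ValueError(f"{path.name}: empty FASTA file")
    return ReferenceDB(merged.values())


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> None:
    """Write a reference DB as FASTA (one entry per collapsed duplicate)."""
    with open(path, "w") as fh:
        for r in db.records:
            for k in range(r.multiplicity):
                rid = r.record_id if k == 0 else f"{r.record_id}.dup{k}"
                fh.write(f">{rid} {r.species}\n{r.sequence}\n")


def eligible_species_for_split(db: ReferenceDB, min_unique: int = 2) -> set[str]:
    """Species with at least ``min_unique`` distinct sequence strings."""
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    return {sp for sp, n in db.unique_sequence_counts().items() if n >= min_unique}


def split_train_holdout(
    db: ReferenceDB,
    min_unique: int = 2,
    seed: int | np.random.Generator = 0,
    holdout_per_species: int = 1,
) -> tuple[ReferenceDB, ReferenceDB]:
    """Random split-sampling: hold out unique sequences per species.

    For every species, ``holdout_per_species`` randomly chosen distinct
    sequences go to the hold-out set and the remaining records to the
    training set, so both partitions cover all species.  Deterministic
    given ``seed``.

    Raises
    ------
    ValueError
        If the DB contains a species with fewer than ``min_unique`` unique
        sequences (filter with :func:`eligible_species_for_split` first),
        or if ``holdout_per_species`` would exhaust a species.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = eligible_species_for_split(db, min_unique)
    missing = set(db.label_index) - eligible
    if missing:
        raise ValueError(
            f"{len(missing)} species with < {min_unique} unique sequences "
            f"present (e.g. {sorted(missing)[0]!r}); filter them out first"
        )
    train: list[ReferenceRecord] = []
    holdout: list[ReferenceRecord] = []
    for sp in sorted(eligible):
        uniq = sorted({r.sequence for r in db.records if r.species == sp})
        if holdout_per_species >= len(uniq):
            raise ValueError(
                f"species {sp!r}: cannot hold out {holdout_per_species} of "
                f"{len(uniq)} unique sequences"
            )
        held = set(
            rng.choice(len(uniq), size=holdout_per_species, replace=False).tolist()
        )
        held_seqs = {uniq[i] for i in held}
        for r in db.records:
            if r.species != sp:
                continue
            (holdout if r.sequence in held_seqs else train).append(r)
    return ReferenceDB(train), ReferenceDB(holdout)


# ---------------------------------------------------------------------------
# Tag manifest (ngsfilter-style TSV)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagEntry:
    """Demultiplexing entry for one PCR replicate."""

    sample_id: str
    forward_tag: str
    reverse_tag: str
    forward_primer: str
    reverse_primer: str
    filter_id: str | None = None
    river_id: str | None = None
    experiment: str = "exp"


@dataclass
class TagManifest:
    """Sample -> tag/primer/metadata mapping for one sequencing library."""

    entries: dict[str, TagEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lens = {len(e.forward_tag) for e in self.entries.values()}
        lens |= {len(e.reverse_tag) for e in self.entries.values()}
        if len(lens) > 1:
            raise ValueError(f"inconsistent tag lengths in manifest: {sorted(lens)}")
        pairs: dict[tuple[str, str], str] = {}
        for e in self.entries.values():
            key = (e.forward_tag, e.reverse_tag)
            if key in pairs:
                raise ValueError(
                    f"duplicate tag pair {e.forward_tag}:{e.reverse_tag} for "
                    f"samples {pairs[key]!r} and {e.sample_id!r}"
                )
            pairs[key] = e.sample_id

    @property
    def tag_len(self) -> int:
        if not self.entries:
            raise ValueError("empty manifest")
        return len(next(iter(self.entries.values())).forward_tag)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries)

    def hierarchy(self) -> dict[str, tuple[str | None, str | None]]:
        """sample_id -> (filter_id, river_id)."""
        return {s: (e.filter_id, e.river_id) for s, e in self.entries.items()}


def read_tag_manifest(path: str | Path, tag_len: int | None = None) -> TagManifest:
    """Read an ngsfilter-style TSV manifest.

    Columns: ``experiment  sample  tags(FWD:REV)  forward_primer
    reverse_primer`` followed by optional ``key=value`` metadata tokens
    (``filter=...``, ``river=...``).  Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    entries: dict[str, TagEntry] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(
                    f"{path.name}, line {lineno}: expected >= 5 tab-separated "
                    f"columns, got {len(cols)}"
                )
            experiment, sample, tags, fwd_primer, rev_primer = cols[:5]
            if ":" not in tags:
                raise ValueError(
                    f"{path.name}, line {lineno}: tags must be 'FWD:REV'"
                )
            fwd_tag, rev_tag = (t.strip().upper() for t in tags.split(":", 1))
            meta: dict[str, str] = {}
            for token in cols[5:]:
                token = token.strip()
                if not token:
                    continue
                if "=" not in token:
                    raise ValueError(
                        f"{path.name}, line {lineno}: metadata token "
                        f"{token!r} is not key=value"
                    )
                k, v = token.split("=", 1)
                meta[k.strip()] = v.strip()
            if tag_len is not None and (
                len(fwd_tag) != tag_len or len(rev_tag) != tag_len
            ):
                raise ValueError(
                    f"{path.name}, line {lineno}: tag length != {tag_len}"
                )
            if sample in entries:
                raise ValueError(
                    f"{path.name}, line {lineno}: duplicate sample {sample!r}"
                )
            entries[sample] = TagEntry(
                sample_id=sample,
                forward_tag=fwd_tag,
                reverse_tag=rev_tag,
                forward_primer=fwd_primer.strip().upper(),
                reverse_primer=rev_primer.strip().upper(),
                filter_id=meta.get("filter"),
                river_id=meta.get("river"),
                experiment=experiment,
            )
    if not entries:
        raise ValueError(f"{path.name}: no manifest entries")
    return TagManifest(entries)


def write_tag_manifest(manifest: TagManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# experiment\tsample\ttags\tforward_primer\treverse_primer\tmetadata\n")
        for e in manifest.entries.values():
            extras = []
            if e.filter_id is not None:
                extras.append(f"filter={e.filter_id}")
            if e.river_id is not None:
                extras.append(f"river={e.river_id}")
            cols = [
                e.experiment,
                e.sample_id,
                f"{e.forward_tag}:{e.reverse_tag}",
                e.forward_primer,
                e.reverse_primer,
                *extras,
            ]
            fh.write("\t".join(cols) + "\n")


def save_label_index(label_index: dict[str, int], path: str | Path) -> None:
    """Write the species -> class-integer index as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(label_index, fh, indent=1, sort_keys=True)


def load_label_index(path: str | Path) -> dict[str, int]:
    with open(path) as fh:
        idx = json.load(fh)
    values = sorted(idx.values())
    if values != list(range(len(idx))):
        raise ValueError(f"{path}: class integers are not dense 0..C-1")
    return {str(k): int(v) for k, v in idx.items()}
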