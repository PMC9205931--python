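"""Exact-match tag demultiplexing of raw reads.

Pooled libraries mark each PCR replicate with a short (8-bp) tag ligated
before the primer; up to two attachment bases from the plate chemistry
are often read before the tag, so the tag sits at a small, variable
offset from the read start.  Demultiplexing is therefore a handful of
exact hash-table look-ups — one per candidate offset (default offsets
0..4) — with **no** tag error correction: a read whose tag carries a
sequencing error stays unassigned.  Reverse-complement tags map to the
same sample so reverse-oriented reads demultiplex without modification.
"""

from __future__ import annotations

import gzip
from collections import Counter
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .refdb import TagManifest
from .seqcodec import reverse_complement

__all__ = ["UNASSIGNED", "build_tag_table", "assign_read", "demux_fastq"]

#: Bucket name for reads no tag look-up could place.
UNASSIGNED = "UNASSIGNED"


def build_tag_table(manifest: TagManifest) -> dict[str, str]:
    """Map every tag and tag reverse-complement to its sample id.

    Palindromic tags contribute a single key.  A collision — one key
    claimed by two samples, including a tag equal to another sample's
    reverse-complement — is rejected at build time.
    """
    table: dict[str, str] = {}
    for sample, entry in manifest.entries.items():
        if sample == UNASSIGNED:
            raise ValueError(f"sample id {UNASSIGNED!r} is reserved")
        keys = {
            entry.forward_tag,
            reverse_complement(entry.forward_tag),
            entry.reverse_tag,
            reverse_complement(entry.reverse_tag),
        }
        for key in keys:
            owner = table.get(key)
            if owner is not None and owner != sample:
                raise ValueError(
                    f"tag collision: key {key!r} claimed by both "
                    f"{owner!r} and {sample!r}"
                )
            table[key] = sample
    return table


def assign_read(
    read: str,
    table: dict[str, str],
    tag_len: int = 8,
    max_offset: int = 5,
) -> str:
    """Assign a read by exact tag look-up at offsets ``0..max_offset-1``.

    The first matching offset wins; no mismatch is tolerated.  Returns the
    sample id or :data:`UNASSIGNED`.
    """
    read = read.upper()
    for o in range(max_offset):
        key = read[o : o + tag_len]
        if len(key) < tag_len:
            break
        sample = table.get(key)
        if sample is not None:
            return sample
    return UNASSIGNED


def demux_fastq(
    fastq_path: str | Path,
    manifest: TagManifest,
    tag_len: int | None = None,
    max_offset: int = 5,
) -> tuple[dict[str, list[str]], Counter]:
    """Split a FASTQ(.gz) file into per-sample read lists.

    Returns ``(buckets, counts)``: ``buckets[sample]`` is the list of read
    sequences assigned to that sample (including an ``UNASSIGNED``
    bucket), and ``counts`` tallies every bucket, so the counts always sum
    to the number of input reads.

    Raises
    ------
    ValueError
        On a malformed FASTQ record, reporting its index.
    """
    table = build_tag_table(manifest)
    tl = tag_len if tag_len is not None else manifest.tag_len
    buckets: dict[str, list[str]] = {s: [] for s in manifest.sample_ids}
    buckets[UNASSIGNED] = []
    counts: Counter = Counter({s: 0 for s in buckets})
    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    record_index = 0
    with opener(path, "rt") as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                record_index += 1
                sample = assign_read(seq, table, tl, max_offset)
                buckets[sample].append(seq.upper())
                counts[sample] += 1
        except ValueError as exc:
            raise ValueError(
                f"{path.name}: malformed FASTQ near record {record_index + 1}: {exc}"
            ) from None
    return buckets, counts
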