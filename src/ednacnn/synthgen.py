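"""Synthetic reference databases, tag manifests and raw read sets.

Every stage of the pipeline is testable without access to field data:
the generator emulates a short-amplicon (default 60 bp) barcode database
with a handful of intra-species variants per species, a tagged multi-
sample sequencing library, and 150-bp single-end raw reads with the full
``attachment + tag + primer + amplicon + rc(reverse primer) + rc(tag) +
adapter`` layout, recording per-read ground truth.

Tag design follows standard multiplex-identifier practice: tags (and
their reverse complements) keep pairwise Hamming distance >= 3 and share
no suffix/prefix overlap of length 4-7, so offset-scanning exact-match
demultiplexing can neither confuse a one-error tag with another sample
nor hit a spurious window inside a shifted read start.

Synthetic species are drawn independently and are therefore far more
divergent than real congeners sharing a conserved marker; tests passing
on these data demonstrate the machinery, not marker-level resolution on
closely related taxa.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import gzip

import numpy as np
import pandas as pd

from .augment import TELEO_FORWARD_PRIMER, TELEO_REVERSE_PRIMER
from .pipeline import SampleTable
from .refdb import ReferenceDB, ReferenceRecord, TagEntry, TagManifest
from .seqcodec import reverse_complement

__all__ = [
    "simulate_reference_db",
    "simulate_tag_manifest",
    "simulate_raw_fastq",
    "truth_sample_table",
]

_CANON = "ACGT"

#: Constant adapter-like filler emulating read-through past the insert.
ADAPTER_FILL = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC" * 8


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_CANON[i] for i in rng.integers(0, 4, size=length))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mutate_positions(seq: str, k: int, rng: np.random.Generator) -> str:
    if k == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=k, replace=False):
        others = _CANON.replace(chars[pos], "")
        chars[pos] = others[rng.integers(3)]
    return "".join(chars)


def simulate_reference_db(
    n_species: int = 50,
    amplicon_len: int = 60,
    min_divergence: float = 0.1,
    seqs_per_species_range: tuple[int, int] = (1, 10),
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[ReferenceDB, dict]:
    """Generate a species-labelled amplicon database with known structure.

    Species consensus sequences are drawn uniformly at random and accepted
    only if their pairwise Hamming divergence is at least
    ``min_divergence`` (as a fraction of positions).  Each species gets a
    uniform count of variants in ``seqs_per_species_range``, each variant
    differing from the consensus at up to ``min_divergence / 2`` of the
    positions.  Deterministic given ``seed``.

    Returns ``(db, meta)`` where ``meta`` holds the consensus sequences
    and per-species variant counts.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0.0 <= min_divergence <= 1.0:
        raise ValueError("min_divergence must be in [0, 1]")
    lo, hi = seqs_per_species_range
    if lo < 1 or hi < lo:
        raise ValueError("seqs_per_species_range must be (lo >= 1, hi >= lo)")
    rng = np.random.default_rng(seed)
    min_dist = int(np.ceil(min_divergence * amplicon_len))
    if min_dist > amplicon_len:
        raise ValueError("min_divergence infeasible for this amplicon length")
    consensus: list[str] = []
    for _ in range(n_species):
        for attempt in range(max_tries):
            cand = _random_seq(rng, amplicon_len)
            if all(_hamming(cand, c) >= min_dist for c in consensus):
                consensus.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {n_species} sequences of length "
                f"{amplicon_len} at divergence >= {min_divergence}"
            )
    width = len(str(n_species))
    records: list[ReferenceRecord] = []
    meta_consensus: dict[str, str] = {}
    n_variants: dict[str, int] = {}
    max_mut = int(min_divergence / 2 * amplicon_len)
    for i, cons in enumerate(consensus):
        sp = f"sp{i + 1:0{width}d}"
        meta_consensus[sp] = cons
        n_var = int(rng.integers(lo, hi + 1))
        n_variants[sp] = n_var
        for j in range(n_var):
            k = int(rng.integers(0, max_mut + 1))
            records.append(
                ReferenceRecord(f"{sp}_v{j + 1}", sp, _mutate_positions(cons, k, rng))
            )
    db = ReferenceDB(records)
    return db, {"consensus": meta_consensus, "n_variants": n_variants}


def _tag_keys(tag: str) -> set[str]:
    return {tag, reverse_complement(tag)}


def _tags_compatible(keys_a: set[str], keys_b: set[str], tag_len: int) -> bool:
    for ka in keys_a:
        for kb in keys_b:
            if ka != kb and _hamming(ka, kb) < 3:
                return False
            for d in range(1, min(5, tag_len)):
                if ka[d:] == kb[: tag_len - d] or kb[d:] == ka[: tag_len - d]:
                    return False
    return True


def simulate_tag_manifest(
    n_rivers: int = 1,
    filters_per_river: int = 1,
    replicates_per_filter: int = 1,
    tag_len: int = 8,
    seed: int = 0,
    forward_primer: str = TELEO_FORWARD_PRIMER,
    reverse_primer: str = TELEO_REVERSE_PRIMER,
    max_tries: int = 20000,
) -> TagManifest:
    """Generate a nested river/filter/replicate manifest with robust tags.

    One PCR replicate = one sample; each gets a single tag used on both
    ends (forward tag = reverse tag).  Tags satisfy the distance and
    overlap constraints described in the module docstring.
    """
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    keysets: list[set[str]] = []
    n_samples = n_rivers * filters_per_river * replicates_per_filter
    for _ in range(n_samples):
        for attempt in range(max_tries):
            cand = _random_seq(rng, tag_len)
            keys = _tag_keys(cand)
            if len(keys) < 2:  # palindromic tags collide with themselves
                continue
            if not _tags_compatible(keys, keys, tag_len):
                # self suffix/prefix overlap (tag vs its own shifts / RC)
                continue
            if all(_tags_compatible(keys, ks, tag_len) for ks in keysets):
                accepted.append(cand)
                keysets.append(keys)
                break
        else:
            raise ValueError(
                f"could not design {n_samples} robust tags of length {tag_len}"
            )
    entries: dict[str, TagEntry] = {}
    i = 0
    for r in range(1, n_rivers + 1):
        river = f"R{r}"
        for f in range(1, filters_per_river + 1):
            filt = f"{river}_F{f}"
            for p in range(1, replicates_per_filter + 1):
                sample = f"{filt}_P{p}"
                entries[sample] = TagEntry(
                    sample_id=sample,
                    forward_tag=accepted[i],
                    reverse_tag=accepted[i],
                    forward_primer=forward_primer,
                    reverse_primer=reverse_primer,
                    filter_id=filt,
                    river_id=river,
                )
                i += 1
    return TagManifest(entries)


def simulate_raw_fastq(
    db: ReferenceDB,
    manifest: TagManifest,
    composition: Mapping[str, Mapping[str, float]],
    n_reads: int,
    out_fastq: str | Path,
    error_rate: float = 0.0,
    revcomp_fraction: float = 0.0,
    read_len: int = 150,
    seed: int = 0,
    indel_errors: bool = False,
) -> pd.DataFrame:
    """Write a synthetic raw FASTQ file and return its per-read truth table.

    Each read picks a sample uniformly and a species from that sample's
    ``composition`` weights, then one reference variant of the species
    uniformly.  Forward layout: ``attachment(0-2 random bases) + tag +
    forward primer + amplicon + rc(reverse primer) + rc(tag) +
    attachment + adapter``, truncated to ``read_len``; a
    ``revcomp_fraction`` of reads use the mirror-image reverse
    orientation (reverse tag and primer first).  Substitution sequencing
    errors hit the amplicon at ``error_rate`` per position (uniform
    different base); optional single indel errors behind
    ``indel_errors``.  Quality strings are constant ``'I'`` (qualities
    are not used downstream).

    Returns a DataFrame with columns ``read_id, sample_id, species``.
    """
    if not 0.0 <= error_rate <= 1.0 or not 0.0 <= revcomp_fraction <= 1.0:
        raise ValueError("error_rate and revcomp_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = list(composition)
    unknown = set(samples) - set(manifest.sample_ids)
    if unknown:
        raise ValueError(f"composition samples not in manifest: {sorted(unknown)[:3]}")
    by_species = db.sequences_by_species()
    weights: dict[str, tuple[list[str], np.ndarray]] = {}
    for s, comp in composition.items():
        sps = list(comp)
        missing = [sp for sp in sps if sp not in by_species]
        if missing:
            raise ValueError(f"species not in reference DB: {missing[:3]}")
        w = np.asarray([comp[sp] for sp in sps], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError(f"sample {s!r}: weights must be non-negative, not all zero")
        weights[s] = (sps, w / w.sum())

    path = Path(out_fastq)
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    qual = "I" * read_len
    with opener(path, "wt") as fh:
        for i in range(n_reads):
            sample = samples[int(rng.integers(len(samples)))]
            sps, w = weights[sample]
            sp = sps[int(rng.choice(len(sps), p=w))]
            variants = by_species[sp]
            amplicon = variants[int(rng.integers(len(variants)))]
            if error_rate > 0:
                hits = np.flatnonzero(rng.random(len(amplicon)) < error_rate)
                if hits.size:
                    chars = list(amplicon)
                    for pos in hits:
                        others = _CANON.replace(chars[pos], "") or _CANON
                        chars[pos] = others[rng.integers(len(others))]
                    amplicon = "".join(chars)
            if indel_errors and rng.random() < error_rate:
                pos = int(rng.integers(len(amplicon)))
                if rng.random() < 0.5:
                    amplicon = amplicon[:pos] + amplicon[pos + 1 :]
                else:
                    amplicon = (
                        amplicon[:pos]
                        + _CANON[rng.integers(4)]
                        + amplicon[pos:]
                    )
            entry = manifest.entries[sample]
            attach5 = _random_seq(rng, int(rng.integers(0, 3)))
            attach3 = _random_seq(rng, int(rng.integers(0, 3)))
            if rng.random() < revcomp_fraction:
                body = (
                    attach5
                    + entry.reverse_tag
                    + entry.reverse_primer
                    + reverse_complement(amplicon)
                    + reverse_complement(entry.forward_primer)
                    + reverse_complement(entry.forward_tag)
                    + attach3
                )
            else:
                body = (
                    attach5
                    + entry.forward_tag
                    + entry.forward_primer
                    + amplicon
                    + reverse_complement(entry.reverse_primer)
                    + reverse_complement(entry.reverse_tag)
                    + attach3
                )
            read = (body + ADAPTER_FILL)[:read_len]
            read_id = f"r{i:07d}"
            fh.write(f"@{read_id}\n{read}\n+\n{qual}\n")
            rows.append((read_id, sample, sp))
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "species"])


def truth_sample_table(truth: pd.DataFrame, manifest: TagManifest) -> SampleTable:
    """Ground-truth :class:`SampleTable` from a simulator truth table."""
    counts = (
        truth.groupby(["sample_id", "species"], as_index=False)
        .size()
        .rename(columns={"size": "reads"})
    )
    return SampleTable(counts, manifest.hierarchy(), {"mode": "truth"})
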