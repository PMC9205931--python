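"""End-to-end read processing: FASTQ -> per-sample species read counts.

``run_raw`` composes demultiplexing, thresholded classification and a
minimum-read filter into a single pass from a raw FASTQ file to a
:class:`SampleTable`.  ``run_clean`` does the same for reads that are
already demultiplexed (one read list per sample).  A table records read
counts per (PCR replicate, species); the replicate -> filter -> river
hierarchy lets the same table be aggregated to filtration-capsule or
river level, with the minimum-read filter always applied at the
replicate level first.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .demux import UNASSIGNED, demux_fastq
from .evalthresh import REJECTED, classify_with_threshold
from .model import TrainedClassifier
from .refdb import TagManifest

__all__ = [
    "SampleTable",
    "classify_reads",
    "apply_min_reads",
    "aggregate",
    "run_raw",
    "run_clean",
]

_LEVELS = ("replicate", "filter", "river")


@dataclass
class SampleTable:
    """Species x read-count matrix keyed by PCR replicate.

    ``counts`` is a long-format frame with columns ``sample_id, species,
    reads`` (non-negative integers, zero rows dropped); ``hierarchy``
    maps every sample to its ``(filter_id, river_id)``; ``meta`` records
    the parameters and audit counts of the run that produced the table.
    """

    counts: pd.DataFrame
    hierarchy: dict[str, tuple[str | None, str | None]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["sample_id", "species", "reads"]
        if list(self.counts.columns[:3]) != required:
            self.counts = self.counts.reindex(columns=required)
        if len(self.counts):
            reads = self.counts["reads"]
            if (reads < 0).any():
                raise ValueError("read counts must be non-negative")
            if not np.issubdtype(reads.dtype, np.integer):
                if not np.allclose(reads, reads.astype(int)):
                    raise ValueError("read counts must be integers")
                self.counts["reads"] = reads.astype(int)
        self.counts = self.counts[self.counts["reads"] > 0].reset_index(drop=True)
        missing = set(self.counts["sample_id"]) - set(self.hierarchy)
        if missing:
            raise ValueError(f"samples missing from hierarchy: {sorted(missing)[:3]}")

    # -- views -------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.hierarchy)

    @property
    def species(self) -> list[str]:
        return sorted(self.counts["species"].unique())

    def total_reads(self) -> int:
        return int(self.counts["reads"].sum())

    def wide(self) -> pd.DataFrame:
        """Samples x species pivot with zeros for absences."""
        if not len(self.counts):
            return pd.DataFrame(index=self.sample_ids)
        return (
            self.counts.pivot_table(
                index="sample_id", columns="species", values="reads",
                aggfunc="sum", fill_value=0,
            )
            .reindex(self.sample_ids, fill_value=0)
            .astype(int)
        )

    def counts_for(self, sample_id: str) -> dict[str, int]:
        sel = self.counts[self.counts["sample_id"] == sample_id]
        return dict(zip(sel["species"], sel["reads"].astype(int)))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Long-format TSV (sample_id, filter_id, river_id, species, reads)
        plus an optional JSON metadata sidecar."""
        rows = []
        for _, row in self.counts.iterrows():
            f, r = self.hierarchy[row["sample_id"]]
            rows.append((row["sample_id"], f or "", r or "", row["species"], row["reads"]))
        # emit empty samples too so the hierarchy round-trips
        seen = set(self.counts["sample_id"])
        for s in self.sample_ids:
            if s not in seen:
                f, r = self.hierarchy[s]
                rows.append((s, f or "", r or "", "", 0))
        pd.DataFrame(
            rows, columns=["sample_id", "filter_id", "river_id", "species", "reads"]
        ).to_csv(path, sep="\t", index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=1, default=str)

    @classmethod
    def from_tsv(cls, path: str | Path, meta: dict | None = None) -> "SampleTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str},
                         keep_default_na=False)
        hierarchy = {}
        for _, row in df.iterrows():
            hierarchy[row["sample_id"]] = (
                row.get("filter_id") or None,
                row.get("river_id") or None,
            )
        counts = df[df["species"] != ""][["sample_id", "species", "reads"]]
        return cls(counts.reset_index(drop=True), hierarchy, meta or {})


def classify_reads(
    reads: Sequence[str],
    classifier: TrainedClassifier,
    t: float,
    batch_size: int = 2048,
) -> tuple[Counter, int, int]:
    """Thresholded per-species read counts for one read collection.

    Returns ``(counts, n_rejected, n_skipped)`` where ``counts[species]``
    is the number of reads whose thresholded label is that species,
    ``n_rejected`` counts below-threshold reads and ``n_skipped`` counts
    unclassifiable (invalid-character) reads.  Their sum equals
    ``len(reads)``.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    species = classifier.species
    counts: Counter = Counter()
    n_rejected = 0
    n_skipped = 0
    for start in range(0, len(reads), batch_size):
        chunk = list(reads[start : start + batch_size])
        probs = classifier.predict_proba(chunk, batch_size=batch_size)
        skipped = np.isnan(probs[:, 0])
        n_skipped += int(skipped.sum())
        labels = classify_with_threshold(probs[~skipped], t)
        n_rejected += int((labels == REJECTED).sum())
        accepted = labels[labels != REJECTED]
        if accepted.size:
            binc = np.bincount(accepted, minlength=len(species))
            for ci in np.flatnonzero(binc):
                counts[species[ci]] += int(binc[ci])
    return counts, n_rejected, n_skipped


def apply_min_reads(table: SampleTable, min_reads: int) -> SampleTable:
    """Zero out, per PCR replicate, species with fewer than ``min_reads``.

    ``min_reads=0`` is the identity; composing filters keeps only the
    strictest one (idempotent composition).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    counts = table.counts[table.counts["reads"] >= min_reads].reset_index(drop=True)
    meta = dict(table.meta)
    meta["min_reads"] = max(min_reads, int(meta.get("min_reads", 0)))
    return SampleTable(counts.copy(), dict(table.hierarchy), meta)


def aggregate(table: SampleTable, level: str) -> SampleTable:
    """Sum counts within the requested grouping (replicate/filter/river).

    Replicate level is the identity.  Aggregated tables re-key samples by
    the group id and preserve read totals.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {_LEVELS}")
    if level == "replicate":
        return SampleTable(table.counts.copy(), dict(table.hierarchy), dict(table.meta))
    pos = 0 if level == "filter" else 1
    group: dict[str, str] = {}
    for sample, (f, r) in table.hierarchy.items():
        gid = (f, r)[pos]
        if gid is None:
            raise ValueError(f"sample {sample!r} has no {level} id")
        group[sample] = gid
    counts = table.counts.copy()
    if len(counts):
        counts["sample_id"] = counts["sample_id"].map(group)
        counts = (
            counts.groupby(["sample_id", "species"], as_index=False)["reads"].sum()
        )
    hierarchy: dict[str, tuple[str | None, str | None]] = {}
    for sample, (f, r) in table.hierarchy.items():
        gid = group[sample]
        hierarchy[gid] = (gid, r) if level == "filter" else (None, gid)
    meta = dict(table.meta)
    meta["level"] = level
    return SampleTable(counts, hierarchy, meta)


def _table_from_buckets(
    buckets: Mapping[str, Sequence[str]],
    manifest: TagManifest,
    classifier: TrainedClassifier,
    t: float,
    min_reads: int,
    extra_meta: dict,
) -> SampleTable:
    rows = []
    rejected: dict[str, int] = {}
    skipped: dict[str, int] = {}
    for sample in manifest.sample_ids:
        reads = buckets.get(sample, [])
        counts, n_rej, n_skip = classify_reads(reads, classifier, t)
        rejected[sample] = n_rej
        skipped[sample] = n_skip
        for sp, n in sorted(counts.items()):
            rows.append((sample, sp, n))
    meta = {
        "threshold": t,
        "min_reads": 0,
        "classifier": classifier.training_meta.get("seed"),
        "rejected": rejected,
        "skipped": skipped,
        **extra_meta,
    }
    table = SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "species", "reads"]),
        manifest.hierarchy(),
        meta,
    )
    return apply_min_reads(table, min_reads)


def run_raw(
    fastq_path: str | Path,
    manifest: TagManifest,
    classifier: TrainedClassifier,
    t: float = 0.9,
    min_reads: int = 50,
    max_offset: int = 5,
) -> SampleTable:
    """Raw FASTQ -> demultiplex -> thresholded counts -> min-read filter.

    Unassigned reads never contribute counts; rejection, skip and
    unassignment tallies are recorded in ``meta`` for audit.  The result
    is deterministic given the classifier and inputs, and invariant to
    read order.
    """
    buckets, dcounts = demux_fastq(fastq_path, manifest, max_offset=max_offset)
    return _table_from_buckets(
        buckets,
        manifest,
        classifier,
        t,
        min_reads,
        {
            "mode": "raw",
            "fastq": str(fastq_path),
            "unassigned": int(dcounts[UNASSIGNED]),
            "total_reads": int(sum(dcounts.values())),
        },
    )


def _read_sequences(path: Path) -> list[str]:
    fmt = "fastq" if ".fastq" in path.name or ".fq" in path.name else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]


def run_clean(
    sample_reads: Mapping[str, Sequence[str]] | Mapping[str, str | Path],
    manifest: TagManifest,
    classifier: TrainedClassifier,
    t: float = 0.9,
    min_reads: int = 50,
) -> SampleTable:
    """Classify already-demultiplexed reads (one collection per sample).

    Values of ``sample_reads`` may be read lists or paths to per-sample
    FASTA/FASTQ files.  The classifier is the same as in raw mode; only
    demultiplexing is skipped.
    """
    buckets: dict[str, list[str]] = {}
    for sample, reads in sample_reads.items():
        if isinstance(reads, (str, Path)):
            buckets[sample] = _read_sequences(Path(reads))
        else:
            buckets[sample] = list(reads)
    unknown = set(buckets) - set(manifest.sample_ids)
    if unknown:
        raise ValueError(f"samples not in manifest: {sorted(unknown)[:3]}")
    return _table_from_buckets(
        buckets, manifest, classifier, t, min_reads, {"mode": "clean"}
    )
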