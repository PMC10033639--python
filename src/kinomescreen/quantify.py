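"""FASTQ -> raw guide count matrix: barcode demultiplexing and protospacer matching.

Amplicon reads carry a sample barcode (index read or a fixed offset inside the
read) followed by a constant anchor (vector sequence) and the 20-nt
protospacer. Matching is exact by default; an optional 1-mismatch mode uses a
per-guide Hamming neighborhood with ambiguous hits discarded. Quality values
are ignored.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .library import GuideLibrary, SampleSheet

PROTOSPACER_LEN = 20
UNASSIGNED = "__unassigned__"


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase strings) from a plain or gzipped FASTQ."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


@dataclass
class DemuxResult:
    """Per-sample read streams plus the tally of barcode-unmatched reads."""

    streams: dict[str, list[str]]
    unassigned: int = 0
    total: int = 0


def demultiplex(
    reads: Iterable[str],
    sheet: SampleSheet,
    barcode_offset: int = 0,
    strip_barcode: bool = True,
) -> DemuxResult:
    """Route each read to the unique sample whose barcode matches exactly.

    The barcode is the ``barcode_length``-mer at ``barcode_offset`` within the
    read (use a separate index-read stream by passing those sequences as
    ``reads`` with ``strip_barcode=False``). Reads matching no sheet barcode
    are tallied unassigned. Duplicate barcodes are rejected at sheet load.
    """
    bmap = sheet.barcode_map()
    blen = sheet.barcode_length
    end = barcode_offset + blen
    out = DemuxResult(streams={sid: [] for sid in sheet.sample_ids})
    for read in reads:
        out.total += 1
        sid = bmap.get(read[barcode_offset:end]) if len(read) >= end else None
        if sid is None:
            out.unassigned += 1
        else:
            out.streams[sid].append(read[end:] if strip_barcode else read)
    return out


def _hamming1(seq: str) -> Iterator[str]:
    for i, c in enumerate(seq):
        for b in "ACGT":
            if b != c:
                yield seq[:i] + b + seq[i + 1 :]


def _build_lookup(library: GuideLibrary, mismatches: int) -> dict[str, str | None]:
    """protospacer-kmer -> guide_id; None marks an ambiguous 1-mismatch k-mer."""
    lookup: dict[str, str | None] = dict(library.protospacer_map())
    if mismatches == 0:
        return lookup
    if mismatches != 1:
        raise ValueError("only 0 or 1 mismatches supported")
    exact = set(lookup)
    for proto, gid in library.protospacer_map().items():
        for neigh in _hamming1(proto):
            if neigh in exact:
                continue  # exact protospacers always win
            if neigh in lookup and lookup[neigh] != gid:
                lookup[neigh] = None  # claimed by two guides -> ambiguous
            else:
                lookup[neigh] = gid
    return lookup


@dataclass
class CountResult:
    """Raw guide x sample count matrix with per-sample read-fate tallies.

    Conservation holds per sample:
    ``assigned + unassigned + ambiguous + skipped == total``.
    """

    counts: pd.DataFrame
    unassigned: pd.Series
    ambiguous: pd.Series
    skipped: pd.Series
    total: pd.Series

    @property
    def assigned(self) -> pd.Series:
        return self.counts.sum(axis=0)


def count_guides(
    streams: Mapping[str, Iterable[str]],
    library: GuideLibrary,
    anchor: str = "",
    protospacer_offset: int | None = None,
    mismatches: int = 0,
) -> CountResult:
    """Count protospacer matches per guide per sample.

    A read increments guide *g* iff the 20-mer immediately following the first
    occurrence of ``anchor`` (or at the fixed ``protospacer_offset`` when no
    anchor is given) equals *g*'s protospacer (optionally within Hamming
    distance 1, ambiguous hits discarded). Reads too short to contain the
    window are skipped and tallied.
    """
    if not anchor and protospacer_offset is None:
        raise ValueError("provide a nonempty anchor or a protospacer_offset")
    lookup = _build_lookup(library, mismatches)
    guide_ids = list(library.guide_ids)
    counts = pd.DataFrame(0, index=guide_ids, columns=list(streams), dtype=int)
    unassigned, ambiguous, skipped, total = ({} for _ in range(4))
    for sample, reads in streams.items():
        n_un = n_amb = n_skip = n_tot = 0
        tally = counts[sample]
        for read in reads:
            n_tot += 1
            if anchor:
                pos = read.find(anchor)
                start = pos + len(anchor) if pos >= 0 else -1
            else:
                start = protospacer_offset  # type: ignore[assignment]
            if start is None or start < 0 or len(read) < start + PROTOSPACER_LEN:
                n_skip += 1
                continue
            hit = lookup.get(read[start : start + PROTOSPACER_LEN], UNASSIGNED)
            if hit is UNASSIGNED or hit == UNASSIGNED:
                n_un += 1
            elif hit is None:
                n_amb += 1
            else:
                tally[hit] += 1
        unassigned[sample], ambiguous[sample] = n_un, n_amb
        skipped[sample], total[sample] = n_skip, n_tot
    return CountResult(
        counts=counts,
        unassigned=pd.Series(unassigned, dtype=int),
        ambiguous=pd.Series(ambiguous, dtype=int),
        skipped=pd.Series(skipped, dtype=int),
        total=pd.Series(total, dtype=int),
    )


def quantify_fastq(
    fastq: str | Path,
    library: GuideLibrary,
    sheet: SampleSheet,
    anchor: str,
    barcode_offset: int = 0,
    mismatches: int = 0,
) -> CountResult:
    """Demultiplex a multiplexed FASTQ and count guides in one pass."""
    demux = demultiplex(iter_fastq(fastq), sheet, barcode_offset=barcode_offset)
    return count_guides(demux.streams, library, anchor=anchor, mismatches=mismatches)
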