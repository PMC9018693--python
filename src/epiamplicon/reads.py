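"""Read merging, format conversion and pre-call quality filtering.

Paired-end amplicon reads are assembled into a single molecule sequence by
an exhaustive suffix-prefix overlap scan (the reverse read is
reverse-complemented first). The consensus contract is deliberately simple
and fully specified: among overlaps of at least ``min_overlap`` bases whose
mismatch fraction is within ``max_mismatch_frac``, the one with the lowest
mismatch fraction wins, ties broken by the longest overlap; mismatched
positions are resolved in favour of the forward read. Merged reads are then
length/N/primer filtered against the bisulfite-converted reference before
methylation calling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconSpec, reverse_complement


@dataclass(frozen=True)
class MergedRead:
    """One assembled molecule sequence."""

    sample_id: str
    seq: str
    source: str = "merged"  # "merged" | "pre-merged"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("merged read sequence must be non-empty")
        if set(self.seq) - set("ACGTN"):
            raise ValueError("merged read alphabet must be within ACGTN")


@dataclass(frozen=True)
class MergeRejection:
    """Value returned when no acceptable overlap exists (not an error)."""

    reason: str = "no_overlap"


def _as_seq(read) -> str:
    if isinstance(read, SeqRecord):
        return str(read.seq).upper()
    return str(read).upper()


def merge_read_pair(
    fw,
    rv,
    min_overlap: int = 40,
    max_mismatch_frac: float = 0.1,
    sample_id: str = "",
) -> MergedRead | MergeRejection:
    """Assemble a forward/reverse read pair into one sequence.

    ``fw``/``rv`` may be Biopython ``SeqRecord``s or plain strings; ``rv``
    is reverse-complemented before the overlap scan. Returns a
    :class:`MergeRejection` (a value, not an exception) when no overlap of
    at least ``min_overlap`` bases has mismatch fraction within
    ``max_mismatch_frac``.
    """
    f = _as_seq(fw)
    r = reverse_complement(_as_seq(rv))
    if not f or not r:
        raise ValueError("reads must be non-empty")
    nf, nr = len(f), len(r)
    fa = np.frombuffer(f.encode(), dtype=np.uint8)
    ra = np.frombuffer(r.encode(), dtype=np.uint8)

    best = None  # (mismatch_frac, -overlap, merged)
    max_l = min(nf, nr)
    for L in range(min_overlap, max_l + 1):
        mm = int((fa[nf - L :] != ra[:L]).sum())
        frac = mm / L
        if frac > max_mismatch_frac:
            continue
        key = (frac, -L)
        if best is None or key < best[0]:
            merged = f[: nf - L] + f[nf - L :] + r[L:]  # fw wins overlap
            best = (key, merged)
    if best is None:
        return MergeRejection()
    return MergedRead(sample_id=sample_id, seq=best[1], source="merged")


def merge_read_pairs(
    pairs: Iterable[tuple],
    min_overlap: int = 40,
    max_mismatch_frac: float = 0.1,
    sample_id: str = "",
) -> tuple[list[MergedRead], int]:
    """Vectorised batch merge for many pairs of identical read lengths.

    Groups pairs by (len(fw), len(rv)) and scans each candidate overlap
    across the whole group at once. Returns ``(merged_reads, n_rejected)``
    with merged reads in input order (rejected pairs omitted).
    """
    seqs = [(_as_seq(a), reverse_complement(_as_seq(b))) for a, b in pairs]
    out: list[MergedRead | None] = [None] * len(seqs)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (f, r) in enumerate(seqs):
        groups.setdefault((len(f), len(r)), []).append(i)
    for (nf, nr), idxs in groups.items():
        F = np.frombuffer(
            "".join(seqs[i][0] for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), nf)
        R = np.frombuffer(
            "".join(seqs[i][1] for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), nr)
        n = len(idxs)
        best_frac = np.full(n, np.inf)
        best_len = np.zeros(n, dtype=int)
        for L in range(min_overlap, min(nf, nr) + 1):
            frac = (F[:, nf - L :] != R[:, :L]).sum(axis=1) / L
            ok = frac <= max_mismatch_frac
            better = ok & (
                (frac < best_frac)
                | ((frac == best_frac) & (L > best_len))
            )
            best_frac[better] = frac[better]
            best_len[better] = L
        for j, i in enumerate(idxs):
            L = int(best_len[j])
            if L == 0:
                continue
            f, r = seqs[i]
            out[i] = MergedRead(
                sample_id=sample_id, seq=f + r[L:], source="merged"
            )
    merged = [m for m in out if m is not None]
    return merged, len(seqs) - len(merged)


def fastq_to_fasta(records: Iterable[SeqRecord]) -> Iterator[SeqRecord]:
    """Drop qualities: FASTQ records become FASTA records, order preserved."""
    for rec in records:
        yield SeqRecord(Seq(str(rec.seq)), id=rec.id, description="")


def write_fastq_pairs(
    pairs: Iterable[tuple[str, str]],
    fw_path: str | Path,
    rv_path: str | Path,
    sample_id: str,
    qual_char: str = "I",
) -> None:
    """Write simulated pairs as two phred+33 4-line FASTQ files."""
    with open(fw_path, "w") as fh1, open(rv_path, "w") as fh2:
        for i, (fw, rv) in enumerate(pairs):
            fh1.write(f"@{sample_id}_{i}/1\n{fw}\n+\n{qual_char * len(fw)}\n")
            fh2.write(f"@{sample_id}_{i}/2\n{rv}\n+\n{qual_char * len(rv)}\n")


def read_fastq_pairs(
    fw_path: str | Path, rv_path: str | Path
) -> list[tuple[SeqRecord, SeqRecord]]:
    """Load a pair of FASTQ files; raises on malformed input (Biopython)."""
    fw = list(SeqIO.parse(str(fw_path), "fastq"))
    rv = list(SeqIO.parse(str(rv_path), "fastq"))
    if len(fw) != len(rv):
        raise ValueError(
            f"paired files differ in record count: {len(fw)} vs {len(rv)}"
        )
    return list(zip(fw, rv))


def _primer_identity(window: str, primer: str) -> float:
    """Identity of a read window against a primer anchor.

    Y/R degeneracy in the primer (bisulfite-ambiguous positions) is
    tolerated: Y matches C or T, R matches A or G.
    """
    if not primer:
        return 0.0
    hits = sum(
        p == w
        or (p == "Y" and w in "CT")
        or (p == "R" and w in "AG")
        for w, p in zip(window, primer)
    )
    return hits / len(primer)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str  # "pass" | "length" | "n_fraction" | "primer"


def quality_filter(
    read: MergedRead,
    spec: AmpliconSpec,
    max_len_dev: float = 0.1,
    max_n_frac: float = 0.02,
    min_primer_score: float = 0.8,
) -> FilterResult:
    """Pre-call filter on length, N content and primer anchors.

    Primer matching is done against the bisulfite-converted primer anchors
    (C-free by design in simulated amplicons); the first/last windows of
    the read must reach ``min_primer_score`` identity on at least one end.
    """
    ref_len = len(spec.reference_seq)
    if abs(len(read.seq) - ref_len) > max_len_dev * ref_len:
        return FilterResult(False, "length")
    n_frac = read.seq.count("N") / len(read.seq)
    if n_frac > max_n_frac:
        return FilterResult(False, "n_fraction")
    fw_score = _primer_identity(read.seq[: len(spec.primer_fw)], spec.primer_fw)
    rv_anchor = reverse_complement(spec.primer_rv)
    rv_score = _primer_identity(read.seq[-len(rv_anchor):], rv_anchor)
    if fw_score < min_primer_score and rv_score < min_primer_score:
        return FilterResult(False, "primer")
    return FilterResult(True, "pass")


def filter_reads(
    reads: Iterable[MergedRead],
    spec: AmpliconSpec,
    **kwargs,
) -> tuple[list[MergedRead], Counter]:
    """Apply :func:`quality_filter` to many reads.

    Returns passing reads and a Counter of outcomes whose values partition
    the input: ``counter["pass"] + sum(failure reasons) == total``.
    """
    kept: list[MergedRead] = []
    report: Counter = Counter()
    for read in reads:
        res = quality_filter(read, spec, **kwargs)
        report[res.reason] += 1
        if res.passed:
            kept.append(read)
    return kept, report
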