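"""Per-molecule methylation calling and bisulfite-conversion QC.

Each filtered read is aligned to the in-silico converted reference of its
amplicon; the bases landing on CpG cytosines become the molecule's binary
epiallele string ('1' = C = methylated, '0' = T = unmethylated), and the
bases landing on non-CpG cytosines give a per-read conversion fraction used
to discard incompletely converted molecules. A separate estimator pools the
fully unmethylated spike-in reads into a sample-level conversion-efficiency
estimate with a binomial confidence interval.

Alignment is done in "three-letter" space: both read and reference are
fully C->T converted before scoring, so a methylated (C) or unmethylated
(T) CpG matches the reference equally. Reads whose length equals the
reference take a direct positional correspondence when its identity clears
the floor; otherwise a global affine-gap alignment (Biopython
PairwiseAligner) resolves indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from scipy.stats import binomtest

from .amplicon import AmpliconSpec
from .reads import MergedRead

_C = ord("C")
_T = ord("T")


@dataclass(frozen=True)
class Correspondence:
    """Per-position mapping of a read onto its amplicon reference.

    ``ref_to_read[i]`` is the read index aligned to reference position
    ``i``, or -1 where the reference position is deleted in the read.
    """

    read_seq: str
    ref_to_read: np.ndarray
    identity: float
    n_gaps: int


def _full_convert_bytes(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == _C] = _T
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # free end gaps on the read: tolerate small terminal truncations
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.target_end_gap_score = 0.0
    return aligner


def align_to_amplicon(
    read: MergedRead | str,
    spec: AmpliconSpec,
    min_identity: float = 0.8,
) -> Correspondence | None:
    """Globally align a merged read to the amplicon; None if it rejects.

    Identity is computed in fully converted (three-letter) space as
    matching reference positions / reference length; reads below
    ``min_identity`` are rejected.
    """
    seq = read.seq if isinstance(read, MergedRead) else str(read)
    ref = spec.reference_seq
    read_b = np.frombuffer(seq.encode(), dtype=np.uint8)
    ref_b = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_c = _full_convert_bytes(read_b)
    ref_c = _full_convert_bytes(ref_b)

    if len(seq) == len(ref):
        matches = int((read_c == ref_c).sum())
        identity = matches / len(ref)
        if identity >= min_identity:
            return Correspondence(
                read_seq=seq,
                ref_to_read=np.arange(len(ref)),
                identity=identity,
                n_gaps=0,
            )
        # fall through: an indel pair may still align above the floor

    aligner = _make_aligner()
    alignment = aligner.align(
        ref_c.tobytes().decode(), read_c.tobytes().decode()
    )[0]
    ref_to_read = np.full(len(ref), -1, dtype=int)
    matches = 0
    n_gaps = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        ref_to_read[t0:t1] = np.arange(q0, q1)
        matches += int((ref_c[t0:t1] == read_c[q0:q1]).sum())
    # count gap openings from the aligned-block structure
    blocks = alignment.aligned[0]
    for i in range(1, len(blocks)):
        if blocks[i][0] != blocks[i - 1][1]:
            n_gaps += 1
    qblocks = alignment.aligned[1]
    for i in range(1, len(qblocks)):
        if qblocks[i][0] != qblocks[i - 1][1]:
            n_gaps += 1
    identity = matches / len(ref)
    if identity < min_identity:
        return None
    return Correspondence(
        read_seq=seq, ref_to_read=ref_to_read, identity=identity,
        n_gaps=n_gaps,
    )


@dataclass(frozen=True)
class ReadCall:
    """Methylation call for one read.

    ``epiallele`` is None when the read was rejected (too many ambiguous
    CpGs or failed alignment); ``read_conversion`` is the fraction of
    non-CpG reference cytosines read as T (bisulfite conversion QC).
    """

    sample_id: str
    epiallele: str | None
    n_ambiguous_cpg: int
    read_conversion: float


def call_epiallele(
    corr: Correspondence,
    spec: AmpliconSpec,
    max_ambiguous: int = 0,
    sample_id: str = "",
) -> ReadCall:
    """Call the per-CpG methylation string from an aligned read.

    C -> '1', T -> '0'; any other base or a deletion is ambiguous. A read
    with more than ``max_ambiguous`` ambiguous CpGs is rejected (its
    profile cannot be placed in the 2^k epiallele space).
    """
    bits = []
    n_ambiguous = 0
    for off in spec.cpg_offsets:
        j = corr.ref_to_read[off]
        base = corr.read_seq[j] if j >= 0 else "-"
        if base == "C":
            bits.append("1")
        elif base == "T":
            bits.append("0")
        else:
            bits.append("?")
            n_ambiguous += 1
    converted = total = 0
    for off in spec.non_cpg_c_offsets:
        j = corr.ref_to_read[off]
        if j < 0:
            continue
        base = corr.read_seq[j]
        if base in "CT":
            total += 1
            converted += base == "T"
    read_conversion = converted / total if total else 0.0
    epiallele = None if n_ambiguous > max_ambiguous else "".join(bits)
    if epiallele is not None and "?" in epiallele:
        # ambiguous CpGs within tolerance: profile still not placeable
        epiallele = None
    return ReadCall(
        sample_id=sample_id,
        epiallele=epiallele,
        n_ambiguous_cpg=n_ambiguous,
        read_conversion=read_conversion,
    )


def call_reads(
    reads: Sequence[MergedRead | str],
    spec: AmpliconSpec,
    sample_id: str = "",
    max_ambiguous: int = 0,
    min_identity: float = 0.8,
) -> list[ReadCall]:
    """Align and call a batch of reads against one amplicon.

    Reads of exactly the reference length are called in one vectorised
    pass (the common case for substitution-only error); others go through
    the general alignment path. Alignment-rejected reads appear as
    ``ReadCall`` with ``epiallele=None`` so report counts stay complete.
    """
    seqs = [r.seq if isinstance(r, MergedRead) else str(r) for r in reads]
    ref = spec.reference_seq
    ref_b = np.frombuffer(ref.encode(), dtype=np.uint8)
    ref_c = _full_convert_bytes(ref_b)
    calls: list[ReadCall | None] = [None] * len(seqs)

    exact = [i for i, s in enumerate(seqs) if len(s) == len(ref)]
    if exact:
        M = np.frombuffer(
            "".join(seqs[i] for i in exact).encode(), dtype=np.uint8
        ).reshape(len(exact), len(ref))
        Mc = _full_convert_bytes(M)
        identity = (Mc == ref_c).mean(axis=1)
        cpg = np.array(spec.cpg_offsets)
        ncc = np.array(spec.non_cpg_c_offsets)
        cpg_bases = M[:, cpg]
        is_meth = cpg_bases == _C
        is_unmeth = cpg_bases == _T
        n_amb = (~(is_meth | is_unmeth)).sum(axis=1)
        conv_bases = M[:, ncc] if ncc.size else np.empty((len(exact), 0))
        tot = np.isin(conv_bases, (_C, _T)).sum(axis=1)
        conv = (conv_bases == _T).sum(axis=1)
        for row, i in enumerate(exact):
            if identity[row] < min_identity:
                calls[i] = None  # retry via general alignment below
                continue
            rc = conv[row] / tot[row] if tot[row] else 0.0
            if n_amb[row] > 0:
                epiallele = None
            else:
                epiallele = "".join("1" if m else "0" for m in is_meth[row])
            calls[i] = ReadCall(
                sample_id=sample_id,
                epiallele=epiallele,
                n_ambiguous_cpg=int(n_amb[row]),
                read_conversion=float(rc),
            )

    for i, s in enumerate(seqs):
        if calls[i] is not None:
            continue
        corr = align_to_amplicon(s, spec, min_identity=min_identity)
        if corr is None:
            calls[i] = ReadCall(
                sample_id=sample_id, epiallele=None,
                n_ambiguous_cpg=spec.n_cpgs, read_conversion=0.0,
            )
        else:
            calls[i] = call_epiallele(
                corr, spec, max_ambiguous=max_ambiguous, sample_id=sample_id
            )
    return calls  # type: ignore[return-value]


def filter_by_conversion(
    calls: Iterable[ReadCall],
    min_read_conversion: float = 0.95,
) -> tuple[list[ReadCall], dict[str, int]]:
    """Discard reads from incompletely converted molecules.

    Unconverted unmethylated cytosines read as C and would inflate
    methylation, so any read whose non-CpG conversion fraction falls below
    the threshold is removed. Returns retained calls and a count report.
    """
    retained: list[ReadCall] = []
    report = {"retained": 0, "low_conversion": 0, "uncalled": 0}
    for call in calls:
        if call.epiallele is None:
            report["uncalled"] += 1
        elif call.read_conversion < min_read_conversion:
            report["low_conversion"] += 1
        else:
            report["retained"] += 1
            retained.append(call)
    return retained, report


@dataclass(frozen=True)
class ConversionEstimate:
    """Pooled spike-in conversion efficiency with a binomial 95% CI."""

    efficiency: float | None
    ci_low: float | None
    ci_high: float | None
    n_sites: int
    n_reads: int

    @property
    def available(self) -> bool:
        return self.efficiency is not None


def estimate_conversion_efficiency(
    spikein_reads: Sequence[str],
    spikein_ref: str,
    min_identity: float = 0.8,
) -> ConversionEstimate:
    """Estimate bisulfite conversion efficiency from unmethylated spike-in.

    Every cytosine of the spike-in reference is unmethylated, so the
    pooled fraction of reference C positions read as T across all aligned
    reads estimates the conversion rate. Reads that do not align above
    ``min_identity`` are skipped; with no aligned reads an explicit
    no-estimate result is returned.
    """
    ref_b = np.frombuffer(spikein_ref.encode(), dtype=np.uint8)
    c_pos = np.flatnonzero(ref_b == _C)
    converted = 0
    total = 0
    n_aligned = 0
    spec_like_len = len(spikein_ref)
    exact = [s for s in spikein_reads if len(s) == spec_like_len]
    others = [s for s in spikein_reads if len(s) != spec_like_len]
    if exact:
        M = np.frombuffer("".join(exact).encode(), dtype=np.uint8).reshape(
            len(exact), spec_like_len
        )
        Mc = _full_convert_bytes(M)
        refc = _full_convert_bytes(ref_b)
        identity = (Mc == refc).mean(axis=1)
        ok = identity >= min_identity
        n_aligned += int(ok.sum())
        bases = M[np.flatnonzero(ok)][:, c_pos]
        valid = np.isin(bases, (_C, _T))
        total += int(valid.sum())
        converted += int((bases == _T).sum())
    for s in others:
        # general path for length-divergent reads via a throwaway spec-less
        # alignment: reuse the aligner in three-letter space
        aligner = _make_aligner()
        sc = s.replace("C", "T")
        refc_s = spikein_ref.replace("C", "T")
        aln = aligner.align(refc_s, sc)[0]
        matches = 0
        ref_to_read = np.full(len(spikein_ref), -1, dtype=int)
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            ref_to_read[t0:t1] = np.arange(q0, q1)
            matches += sum(refc_s[t] == sc[q]
                           for t, q in zip(range(t0, t1), range(q0, q1)))
        if matches / len(spikein_ref) < min_identity:
            continue
        n_aligned += 1
        for p in c_pos:
            j = ref_to_read[p]
            if j < 0:
                continue
            base = s[j]
            if base in "CT":
                total += 1
                converted += base == "T"
    if n_aligned == 0 or total == 0:
        return ConversionEstimate(None, None, None, 0, 0)
    eff = converted / total
    ci = binomtest(converted, total).proportion_ci(confidence_level=0.95)
    return ConversionEstimate(
        efficiency=eff,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_sites=total,
        n_reads=n_aligned,
    )
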