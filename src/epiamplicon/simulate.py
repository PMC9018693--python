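"""Synthetic bisulfite amplicon data generator.

Everything downstream of the sequencer is testable against this module:
it generates amplicon references with a known CpG map, draws ground-truth
per-molecule methylation profiles (epialleles) from a specified mixture,
converts them with configurable bisulfite failure rates, emits overlapping
paired-end reads with substitution sequencing error, simulates a fully
unmethylated spike-in for conversion-efficiency estimation, and couples
qPCR expression values to mean methylation.

Only the bisulfite top strand is simulated: directional amplicon BS-PCR
with strand-specific primers amplifies a single converted strand, so the
opposite strand never reaches the analysis. Read length defaults to 251 nt
(2 x 251 paired-end chemistry); amplicons up to ~460 nt therefore merge
with at least 40 nt of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplicon import AmpliconSpec, reverse_complement

READ_LENGTH = 251
#: constant per-base quality used for all simulated reads (phred+33 'I' = Q40)
QUAL_CHAR = "I"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth epiallele mixture and error model for one sample.

    ``epiallele_probs`` maps binary methylation strings (length = number of
    CpGs, '1' = methylated) to mixture probabilities. ``conversion_rate`` is
    the probability that an *unmethylated* C is deaminated (read as T);
    ``inappropriate_conversion_rate`` the probability that a *methylated*
    CpG C is converted anyway; ``seq_error_rate`` a per-base substitution
    probability applied after conversion.
    """

    epiallele_probs: dict[str, float]
    n_molecules: int
    conversion_rate: float = 1.0
    inappropriate_conversion_rate: float = 0.0
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        for rate, nm in [
            (self.conversion_rate, "conversion_rate"),
            (self.inappropriate_conversion_rate, "inappropriate_conversion_rate"),
            (self.seq_error_rate, "seq_error_rate"),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if not self.epiallele_probs:
            raise ValueError("epiallele_probs must be non-empty")
        lengths = {len(e) for e in self.epiallele_probs}
        if len(lengths) != 1:
            raise ValueError("all epiallele strings must share one length")
        if any(set(e) - {"0", "1"} for e in self.epiallele_probs):
            raise ValueError("epialleles must be binary strings")
        total = sum(self.epiallele_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"epiallele probabilities sum to {total}, not 1")

    @property
    def k(self) -> int:
        return len(next(iter(self.epiallele_probs)))


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one biological sample in the tissue x stage design."""

    sample_id: str
    tissue: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


def make_amplicon_spec(
    n_cpgs: int,
    length: int,
    labels: list[int] | tuple[int, ...],
    seed: int,
    name: str | None = None,
    primer_length: int = 24,
) -> AmpliconSpec:
    """Generate a random amplicon reference with a prescribed CpG geometry.

    The reference contains exactly ``n_cpgs`` CpG dinucleotides at
    well-separated offsets outside the primer anchor zones, plus at least
    ``n_cpgs`` non-CpG cytosines (needed for per-read conversion QC).
    Primer anchors occupy the first and last ``primer_length`` bases; they
    are kept free of cytosines so the bisulfite-converted primer is
    unambiguous. Deterministic given ``seed``.
    """
    labels = tuple(int(x) for x in labels)
    if not 1 <= n_cpgs <= 12:
        raise ValueError("n_cpgs must be between 1 and 12")
    if len(labels) != n_cpgs or list(labels) != sorted(set(labels)):
        raise ValueError("labels must be strictly increasing, one per CpG")
    if length < 20 * n_cpgs:
        raise ValueError(
            f"length {length} cannot host {n_cpgs} CpGs plus primer anchors"
        )
    # shrink primer anchors on short amplicons so the CpG interior fits
    primer_length = min(primer_length, max(6, (length - 6 * n_cpgs) // 4))
    if length < 2 * primer_length + 4 * n_cpgs:
        raise ValueError(
            f"length {length} cannot host {n_cpgs} CpGs plus primer anchors"
        )
    rng = np.random.default_rng(seed)

    interior_lo = primer_length + 1
    interior_hi = length - primer_length - 2  # CpG needs offset+1 in bounds
    span = interior_hi - interior_lo
    # evenly spaced CpG offsets with random jitter; spacing >= 3 avoids CGCG
    base = np.linspace(interior_lo, interior_hi, num=n_cpgs + 2)[1:-1]
    jitter = rng.integers(-span // (4 * n_cpgs) - 1, span // (4 * n_cpgs) + 2,
                          size=n_cpgs)
    offsets = np.sort(base.astype(int) + jitter)
    offsets = np.clip(offsets, interior_lo, interior_hi)
    for i in range(1, n_cpgs):
        if offsets[i] - offsets[i - 1] < 3:
            offsets[i] = offsets[i - 1] + 3
    if offsets[-1] > interior_hi:
        raise ValueError("could not place CpGs with the required separation")

    seq = rng.choice(_BASES, size=length).copy()
    # primer zones: purines/T only, no C (converted primer == primer)
    for zone in (slice(0, primer_length), slice(length - primer_length, length)):
        seq[zone] = rng.choice(np.frombuffer(b"AGT", dtype=np.uint8),
                               size=primer_length)
    # remove accidental CpGs everywhere: rewrite the G of any CG pair
    arr = seq
    for _ in range(10):
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if cg.size == 0:
            break
        arr[cg + 1] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8),
                                 size=cg.size)
    # plant the prescribed CpGs
    for off in offsets:
        arr[off] = ord("C")
        arr[off + 1] = ord("G")
    # guarantee enough standalone (non-CpG) cytosines for conversion QC
    cpg_set = set(int(o) for o in offsets) | set(int(o) + 1 for o in offsets)
    standalone = [
        i for i in range(interior_lo, interior_hi)
        if arr[i] == ord("C") and i not in cpg_set and arr[i + 1] != ord("G")
    ]
    need = max(0, 2 * n_cpgs - len(standalone))
    if need:
        candidates = [
            i for i in range(interior_lo, interior_hi)
            if i not in cpg_set and (i + 1) not in cpg_set
            and arr[i] != ord("C") and arr[i + 1] != ord("G")
            and (i == 0 or arr[i - 1] != ord("C") or True)
        ]
        chosen = rng.choice(np.array(candidates), size=need, replace=False)
        for i in chosen:
            arr[i] = ord("C")
            if arr[i + 1] == ord("G"):
                arr[i + 1] = ord("T")

    ref = arr.tobytes().decode()
    primer_fw = ref[:primer_length]
    primer_rv = reverse_complement(ref[-primer_length:])
    return AmpliconSpec(
        name=name or f"amplicon_{n_cpgs}cpg",
        reference_seq=ref,
        cpg_offsets=tuple(int(o) for o in offsets),
        cpg_labels=labels,
        primer_fw=primer_fw,
        primer_rv=primer_rv,
    )


def sample_molecules(
    spec: AmpliconSpec, mix: MixtureSpec, rng: np.random.Generator | None = None
) -> list[str]:
    """Draw ground-truth epiallele strings for ``mix.n_molecules`` molecules.

    Deterministic given ``mix.seed`` (unless an external ``rng`` is passed).
    """
    if mix.k != spec.n_cpgs:
        raise ValueError(
            f"mixture epialleles have {mix.k} CpGs, amplicon has {spec.n_cpgs}"
        )
    rng = np.random.default_rng(mix.seed) if rng is None else rng
    alleles = sorted(mix.epiallele_probs)
    probs = np.array([mix.epiallele_probs[a] for a in alleles])
    probs = probs / probs.sum()
    idx = rng.choice(len(alleles), size=mix.n_molecules, p=probs)
    return [alleles[i] for i in idx]


def _convert_molecule(
    molecule: str, spec: AmpliconSpec, mix: MixtureSpec, rng: np.random.Generator
) -> str:
    """Stochastic bisulfite conversion + substitution error for one molecule."""
    arr = np.frombuffer(spec.reference_seq.encode(), dtype=np.uint8).copy()
    T = ord("T")
    # unmethylated Cs: all non-CpG Cs plus CpGs with bit 0
    unmeth = list(spec.non_cpg_c_offsets) + [
        off for off, bit in zip(spec.cpg_offsets, molecule) if bit == "0"
    ]
    meth = [off for off, bit in zip(spec.cpg_offsets, molecule) if bit == "1"]
    if unmeth:
        hit = rng.random(len(unmeth)) < mix.conversion_rate
        arr[np.array(unmeth)[hit]] = T
    if meth:
        hit = rng.random(len(meth)) < mix.inappropriate_conversion_rate
        if hit.any():
            arr[np.array(meth)[hit]] = T
    if mix.seq_error_rate > 0:
        err = np.flatnonzero(rng.random(arr.size) < mix.seq_error_rate)
        if err.size:
            # substitute with one of the three other bases
            shift = rng.integers(1, 4, size=err.size)
            cur = np.searchsorted(_BASES, arr[err])
            arr[err] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def bisulfite_convert_and_read(
    molecule: str,
    spec: AmpliconSpec,
    mix: MixtureSpec,
    rng: np.random.Generator | None = None,
    read_length: int = READ_LENGTH,
) -> tuple[str, str]:
    """Convert one molecule and emit a (forward, reverse) read pair.

    The forward read is the first ``read_length`` bases of the converted
    top strand; the reverse read is the reverse complement of the last
    ``read_length`` bases, so the pair overlaps by
    ``2 * read_length - len(amplicon)`` bases. Amplicons shorter than the
    read length yield full-length identical-span pairs.
    """
    if len(molecule) != spec.n_cpgs:
        raise ValueError("molecule length must equal the amplicon CpG count")
    rng = np.random.default_rng(mix.seed) if rng is None else rng
    conv = _convert_molecule(molecule, spec, mix, rng)
    n = min(read_length, len(conv))
    fw = conv[:n]
    rv = reverse_complement(conv[-n:])
    return fw, rv


def simulate_sample_reads(
    spec: AmpliconSpec, mix: MixtureSpec, read_length: int = READ_LENGTH
) -> tuple[list[str], list[tuple[str, str]]]:
    """Ground-truth molecules and their read pairs for one sample.

    Returns ``(molecules, pairs)`` where ``molecules[i]`` is the true
    epiallele of ``pairs[i]``. Bit-reproducible given ``mix.seed``.
    """
    rng = np.random.default_rng(mix.seed)
    molecules = sample_molecules(spec, mix, rng)
    pairs = [
        bisulfite_convert_and_read(m, spec, mix, rng, read_length)
        for m in molecules
    ]
    return molecules, pairs


# Fixed synthetic stand-in for the fully unmethylated phage spike-in
# fragment: C-rich, CpG-free, with primer-like C-free anchors at both ends.
SPIKEIN_NAME = "unmethylated_spikein_synthetic"
SPIKEIN_REFERENCE = (
    "GGTGAAGGGTAATTAGTTGTTGTT"
    "ACCTTAGCATTCAACTTACCATTCAGATTCCATACAACCTTAGATTCCAT"
    "TCATCAATTAGCTTACATTCCAATTCGATTACCATTCAACTTAGCATACA"
    "CCATTAGATTCAACTTCCATTACATTCAGCTTACCATACAATTCCATTAG"
    "AGGTATGTAAGTTTGGTATTGG"
)


def simulate_spikein(
    n_reads: int,
    conversion_rate: float,
    seed: int,
    seq_error_rate: float = 0.0,
) -> tuple[list[str], str]:
    """Reads from the fully unmethylated spike-in control.

    Every C in the reference is unmethylated, so each is read as T with
    probability ``conversion_rate``. Returns ``(reads, reference)``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    ref = np.frombuffer(SPIKEIN_REFERENCE.encode(), dtype=np.uint8)
    c_pos = np.flatnonzero(ref == ord("C"))
    reads = []
    for _ in range(n_reads):
        arr = ref.copy()
        hit = rng.random(c_pos.size) < conversion_rate
        arr[c_pos[hit]] = ord("T")
        if seq_error_rate > 0:
            err = np.flatnonzero(rng.random(arr.size) < seq_error_rate)
            if err.size:
                shift = rng.integers(1, 4, size=err.size)
                cur = np.searchsorted(_BASES, arr[err])
                arr[err] = _BASES[(cur + shift) % 4]
        reads.append(arr.tobytes().decode())
    return reads, SPIKEIN_REFERENCE


@dataclass(frozen=True)
class ExpressionRecord:
    """qPCR Ct values and derived relative expression for one sample."""

    sample_id: str
    transcript: str
    ct_target: float
    ct_housekeeping: tuple[float, ...]
    rel_expr: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ct_housekeeping:
            raise ValueError("at least one housekeeping Ct is required")
        if self.ct_target <= 0 or any(c <= 0 for c in self.ct_housekeeping):
            raise ValueError("Ct values must be finite and positive")
        delta = self.ct_target - float(np.mean(self.ct_housekeeping))
        object.__setattr__(self, "rel_expr", float(2.0 ** (-delta)))


def simulate_expression(
    mean_methylation: dict[str, float],
    coupling: float,
    noise_sd: float,
    seed: int,
    transcript: str = "synthetic_transcript",
    base_expr: float = 1.0,
    hk_ct: float = 20.0,
    n_hk_replicates: int = 2,
) -> list[ExpressionRecord]:
    """Expression records coupled (linearly) to per-sample mean methylation.

    The intended relative expression is ``base_expr + coupling * m`` (floored
    at a small positive value), so with ``coupling < 0`` and ``noise_sd = 0``
    the Pearson correlation between methylation and 2^-dCt is exactly -1.
    Gaussian noise of sd ``noise_sd`` is applied on the Ct scale to both the
    target and the housekeeping wells.
    """
    if not np.isfinite(coupling):
        raise ValueError("coupling must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for sample_id in sorted(mean_methylation):
        m = mean_methylation[sample_id]
        rel = max(base_expr + coupling * m, 1e-6 * base_expr)
        ct_target = hk_ct - float(np.log2(rel)) + rng.normal(0.0, noise_sd)
        hk = tuple(
            hk_ct + rng.normal(0.0, noise_sd) for _ in range(n_hk_replicates)
        )
        records.append(
            ExpressionRecord(
                sample_id=sample_id,
                transcript=transcript,
                ct_target=ct_target,
                ct_housekeeping=hk,
            )
        )
    return records


def bernoulli_mixture(k: int, p: float) -> dict[str, float]:
    """Mixture whose epialleles are i.i.d. Bernoulli(p) bit draws.

    All 2^k profiles get their exact product-Bernoulli probability, so the
    class distribution of the mixture is exactly Binomial(k, p).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    probs: dict[str, float] = {}
    for code in range(2 ** k):
        bits = format(code, f"0{k}b")
        w = bits.count("1")
        probs[bits] = (p ** w) * ((1 - p) ** (k - w))
    total = sum(probs.values())
    return {b: q / total for b, q in probs.items()}


def tissue_stage_mixture(
    k: int,
    tissue: str,
    stage: str,
    n_molecules: int,
    seed: int,
    conversion_rate: float = 0.995,
    inappropriate_conversion_rate: float = 0.005,
    seq_error_rate: float = 0.001,
) -> MixtureSpec:
    """Default demo mixture for one tissue x stage group.

    Mean methylation rises with developmental stage in "brain"
    (P1 -> P60: 0.10 -> 0.35) and falls in "heart" (0.45 -> 0.20),
    mimicking opposite developmental trajectories in the two tissues.
    On top of the Bernoulli background, each tissue carries two
    tissue-specific "signature" epialleles (disjoint between tissues) at
    10% total mass, so that epiallele distributions separate tissues even
    where mean methylation coincides. These mixtures are demo
    configuration, not biological claims.
    """
    stage_idx = {"P1": 0, "P15": 1, "P60": 2}[stage]
    trajectories = {
        "brain": (0.10, 0.22, 0.35),
        "heart": (0.45, 0.30, 0.20),
    }
    p = trajectories[tissue][stage_idx]
    base = bernoulli_mixture(k, p)
    signatures = {
        "brain": ["1" + "0" * (k - 2) + "1", "0" * (k - 2) + "11"],
        "heart": ["01" + "0" * (k - 2), "0" * (k // 2) + "1" * 2 + "0" * (k - k // 2 - 2)],
    }[tissue]
    probs = {b: q * 0.90 for b, q in base.items()}
    for sig in signatures:
        probs[sig] = probs.get(sig, 0.0) + 0.05
    total = sum(probs.values())
    probs = {b: q / total for b, q in probs.items()}
    return MixtureSpec(
        epiallele_probs=probs,
        n_molecules=n_molecules,
        conversion_rate=conversion_rate,
        inappropriate_conversion_rate=inappropriate_conversion_rate,
        seq_error_rate=seq_error_rate,
        seed=seed,
    )
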