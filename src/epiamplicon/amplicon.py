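"""Amplicon reference specifications for targeted bisulfite sequencing.

An :class:`AmpliconSpec` describes one PCR-amplified target region on the
bisulfite top strand: its unconverted reference sequence, the positions of
the CpG cytosines that are interrogated for methylation, their TSS-relative
labels used for presentation, and the primer anchors at either end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def bisulfite_convert(seq: str, keep_offsets: tuple[int, ...] = ()) -> str:
    """Fully convert a top-strand sequence in silico: C becomes T.

    Offsets in ``keep_offsets`` (e.g. methylated CpG cytosines) are left
    as C. This is the deterministic, complete-conversion reference used
    for alignment and primer matching, not the stochastic simulator.
    """
    keep = set(keep_offsets)
    return "".join(
        b if (b != "C" or i in keep) else "T" for i, b in enumerate(seq)
    )


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon with its CpG coordinate map.

    Attributes
    ----------
    name:
        Amplicon identifier (e.g. a promoter region name).
    reference_seq:
        Unconverted top-strand DNA sequence.
    cpg_offsets:
        0-based offsets of the C of each CpG dinucleotide, strictly
        increasing, leftmost = most 5' CpG.
    cpg_labels:
        TSS-relative integer labels, one per CpG (negative = upstream of
        the transcription start site). Presentation-layer only; all
        internal coordinates are 0-based reference offsets.
    primer_fw, primer_rv:
        Primer anchor sequences as they appear on the *converted* strand
        (forward primer sense, reverse primer as its own 5'->3' sequence).
    """

    name: str
    reference_seq: str
    cpg_offsets: tuple[int, ...]
    cpg_labels: tuple[int, ...]
    primer_fw: str
    primer_rv: str
    non_cpg_c_offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        seq = self.reference_seq.upper()
        object.__setattr__(self, "reference_seq", seq)
        object.__setattr__(self, "cpg_offsets", tuple(self.cpg_offsets))
        object.__setattr__(self, "cpg_labels", tuple(self.cpg_labels))
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError("reference_seq must be non-empty DNA over ACGTN")
        if len(self.cpg_offsets) != len(self.cpg_labels):
            raise ValueError("cpg_offsets and cpg_labels must have equal length")
        if list(self.cpg_offsets) != sorted(set(self.cpg_offsets)):
            raise ValueError("cpg_offsets must be strictly increasing")
        for off in self.cpg_offsets:
            if not (0 <= off < len(seq) - 1) or seq[off : off + 2] != "CG":
                raise ValueError(f"offset {off} does not point at a CpG")
        cpg = set(self.cpg_offsets)
        non_cpg = tuple(
            i for i, b in enumerate(seq) if b == "C" and i not in cpg
        )
        object.__setattr__(self, "non_cpg_c_offsets", non_cpg)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    def __len__(self) -> int:
        return len(self.reference_seq)

    def converted_reference(self, methylated: bool = True) -> str:
        """In-silico fully bisulfite-converted reference.

        With ``methylated=True`` CpG cytosines stay C (the fully
        methylated molecule); otherwise every C becomes T.
        """
        keep = self.cpg_offsets if methylated else ()
        return bisulfite_convert(self.reference_seq, keep)

    def label_of(self, cpg_index: int) -> int:
        """TSS-relative label of the ``cpg_index``-th CpG (0-based, 5'->3')."""
        return self.cpg_labels[cpg_index]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reference_seq": self.reference_seq,
            "cpg_offsets": list(self.cpg_offsets),
            "cpg_labels": list(self.cpg_labels),
            "primer_fw": self.primer_fw,
            "primer_rv": self.primer_rv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmpliconSpec":
        return cls(
            name=d["name"],
            reference_seq=d["reference_seq"],
            cpg_offsets=tuple(d["cpg_offsets"]),
            cpg_labels=tuple(d["cpg_labels"]),
            primer_fw=d["primer_fw"],
            primer_rv=d["primer_rv"],
        )
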