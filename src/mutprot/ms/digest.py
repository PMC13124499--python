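"""In-silico tryptic digestion (Trypsin/LysC mix rule).

Cleavage occurs after every K (LysC cleaves K-P) and after every R not
followed by P. Peptides with 0..max_missed missed cleavages are emitted
within the length bounds, with 1-based start offsets in the parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with modification and provenance bookkeeping."""

    sequence: str
    start_offset: int  # 1-based position of sequence[0] in the parent entry
    missed_cleavages: int
    parent_id: str = ""
    modifications: tuple[tuple[int, float], ...] = ()
    is_mutant: bool = False
    mut_offset_in_peptide: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_offset(self) -> int:
        """1-based inclusive end position in the parent entry."""
        return self.start_offset + len(self.sequence) - 1


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that the bond after sequence[i] is cleaved."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa == "K" or (aa == "R" and sequence[i + 1] != "P"):
            sites.append(i)
    return sites


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 30,
    parent_id: str = "",
) -> list[Peptide]:
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if not sequence:
        raise ValueError("empty sequence")
    # fragment boundaries: starts of fully-cleaved peptides
    starts = [0] + [i + 1 for i in cleavage_sites(sequence)]
    ends = starts[1:] + [len(sequence)]  # exclusive ends of fully-cleaved pieces
    peptides = []
    for i, start in enumerate(starts):
        for missed in range(max_missed + 1):
            j = i + missed
            if j >= len(ends):
                break
            pep = sequence[start:ends[j]]
            if min_len <= len(pep) <= max_len:
                peptides.append(
                    Peptide(
                        sequence=pep,
                        start_offset=start + 1,
                        missed_cleavages=missed,
                        parent_id=parent_id,
                    )
                )
    return peptides
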