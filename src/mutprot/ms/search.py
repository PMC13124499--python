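"""Database search with target-decoy competition and site validation.

Each spectrum keeps its single best-scoring candidate (target or decoy)
among peptides whose precursor m/z lies within tolerance, enumerating
Met-oxidation variants up to the variable-modification cap. q-values use
the classic cumulative decoy/target ratio with a running minimum.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace

from .digest import Peptide, digest
from .masses import OXIDATION, peptide_mass
from .match import (
    FRAGMENT_TOL_DA,
    PRECURSOR_TOL_PPM,
    FragmentMatch,
    precursor_within_tol,
    score_psm,
)
from .spectra import Spectrum

MAX_VARIABLE_MODS = 4
FDR_THRESHOLD = 0.01


@dataclass(frozen=True)
class PSM:
    spectrum_id: str
    peptide: Peptide
    score: float
    matched: tuple[FragmentMatch, ...]
    is_decoy: bool
    q_value: float = 1.0
    site_supported: bool = False


def enumerate_mutant_peptides(entry, max_missed: int = 2,
                              min_len: int = 6, max_len: int = 30) -> list[Peptide]:
    """Digest a mutant entry and keep peptides that are mutation evidence.

    Missense: the peptide span must include the substituted offset.
    Frameshift: the span must reach or cross the first shifted residue.
    """
    peptides = []
    for pep in digest(entry.sequence, max_missed, min_len, max_len,
                      parent_id=entry.entry_id):
        covers = (
            pep.start_offset <= entry.mut_offset <= pep.end_offset
            if entry.kind == "missense"
            else pep.end_offset >= entry.mut_offset
        )
        if covers:
            peptides.append(
                replace(
                    pep,
                    is_mutant=True,
                    mut_offset_in_peptide=max(1, entry.mut_offset - pep.start_offset + 1),
                )
            )
    return peptides


def site_determining_ions(peptide_length: int, mut_offset: int) -> set[tuple[str, int]]:
    """Fragments whose mass depends on the residue at ``mut_offset``.

    For a length-n peptide with the mutation at offset m (1-based), these
    are b_i for i >= m and y_j for j >= n - m + 1 (indices run 1..n-1).
    """
    n = peptide_length
    if not 1 <= mut_offset <= n:
        raise ValueError(f"mut_offset {mut_offset} outside 1..{n}")
    ions = {("b", i) for i in range(mut_offset, n)}
    ions |= {("y", j) for j in range(n - mut_offset + 1, n)}
    return ions


def site_supported(psm: PSM, strict: bool = False) -> bool:
    """True when matched fragments localize the mutation.

    Default: at least one matched site-determining ion. Strict mode
    additionally requires every backbone bond covered by some matched b or
    y ion (full-ladder coverage).
    """
    pep = psm.peptide
    if not pep.is_mutant or pep.mut_offset_in_peptide is None:
        raise ValueError("site support is defined only for mutant-peptide PSMs")
    n = len(pep.sequence)
    site_set = site_determining_ions(n, pep.mut_offset_in_peptide)
    matched_keys = {(m.series, m.index) for m in psm.matched}
    if not matched_keys & site_set:
        return False
    if strict:
        covered = set()
        for series, idx in matched_keys:
            covered.add(idx if series == "b" else n - idx)
        if covered != set(range(1, n)):
            return False
    return True


@dataclass
class PeptideIndex:
    """Digested database indexed by neutral peptide mass (mod variants included)."""

    masses: list[float]
    entries: list[tuple[Peptide, tuple[tuple[int, float], ...], bool]]

    @classmethod
    def build(cls, records, max_missed: int = 2, min_len: int = 6, max_len: int = 30,
              max_mods: int = MAX_VARIABLE_MODS) -> "PeptideIndex":
        """records: iterable of DatabaseRecord-like (record_id, sequence, is_decoy, is_mutant, entry)."""
        seen: set[tuple[str, tuple[tuple[int, float], ...], bool]] = set()
        items: list[tuple[float, Peptide, tuple[tuple[int, float], ...], bool]] = []
        for rec in records:
            if rec.is_mutant and rec.entry is not None and not rec.is_decoy:
                peptides = enumerate_mutant_peptides(
                    rec.entry, max_missed, min_len, max_len)
            else:
                peptides = digest(rec.sequence, max_missed, min_len, max_len,
                                  parent_id=rec.record_id)
            for pep in peptides:
                for mods in _oxidation_variants(pep.sequence, max_mods):
                    key = (pep.sequence, mods, rec.is_decoy)
                    if key in seen:
                        continue
                    seen.add(key)
                    mass = peptide_mass(pep.sequence, mods)
                    items.append((mass, replace(pep, modifications=mods), mods, rec.is_decoy))
        items.sort(key=lambda x: x[0])
        return cls(
            masses=[x[0] for x in items],
            entries=[(x[1], x[2], x[3]) for x in items],
        )

    def candidates(self, neutral_mass: float, tol_ppm: float = PRECURSOR_TOL_PPM):
        tol = neutral_mass * tol_ppm / 1e6
        lo = bisect_left(self.masses, neutral_mass - tol)
        hi = bisect_right(self.masses, neutral_mass + tol)
        return self.entries[lo:hi]


def _oxidation_variants(sequence: str,
                        max_mods: int = MAX_VARIABLE_MODS):
    """All Met-oxidation assignments with at most ``max_mods`` oxidations."""
    met_positions = [i + 1 for i, aa in enumerate(sequence) if aa == "M"]
    yield ()
    for k in range(1, min(len(met_positions), max_mods) + 1):
        for combo in itertools.combinations(met_positions, k):
            yield tuple((pos, OXIDATION) for pos in combo)


def search(
    spectra: list[Spectrum],
    db,
    precursor_tol_ppm: float = PRECURSOR_TOL_PPM,
    fragment_tol: float = FRAGMENT_TOL_DA,
    charges: tuple[int, ...] = (2, 3, 4, 5),
    fragment_charges: tuple[int, ...] = (1,),
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 30,
    index: PeptideIndex | None = None,
) -> tuple[list[PSM], list[str]]:
    """Top-1 target-or-decoy search. Returns (PSMs, unidentified spectrum ids)."""
    if index is None:
        index = PeptideIndex.build(db.records, max_missed, min_len, max_len)
    psms: list[PSM] = []
    unidentified: list[str] = []
    from .masses import PROTON

    for spectrum in spectra:
        if spectrum.charge not in charges:
            unidentified.append(spectrum.spectrum_id)
            continue
        neutral = spectrum.precursor_mz * spectrum.charge - spectrum.charge * PROTON
        best: PSM | None = None
        for pep, mods, is_decoy in index.candidates(neutral, precursor_tol_ppm):
            if not precursor_within_tol(
                spectrum, peptide_mass(pep.sequence, mods), precursor_tol_ppm
            ):
                continue
            score, matched = score_psm(
                pep.sequence, spectrum, mods, fragment_charges, fragment_tol
            )
            cand = PSM(
                spectrum_id=spectrum.spectrum_id,
                peptide=pep,
                score=score,
                matched=tuple(matched),
                is_decoy=is_decoy,
            )
            # deterministic tie-break: higher score, then target over decoy,
            # then lexicographic peptide
            if best is None or (
                cand.score,
                not cand.is_decoy,
                cand.peptide.sequence,
            ) > (best.score, not best.is_decoy, best.peptide.sequence):
                best = cand
        if best is None:
            unidentified.append(spectrum.spectrum_id)
        else:
            psms.append(best)
    return psms, unidentified


def estimate_qvalues(psms: list[PSM]) -> list[PSM]:
    """Attach target-decoy q-values.

    FDR at threshold s = #decoys(score >= s) / max(1, #targets(score >= s));
    q-value = running minimum of FDR over descending score. Input order is
    preserved in the returned list.
    """
    if not psms:
        return []
    order = sorted(range(len(psms)),
                   key=lambda i: (-psms[i].score, psms[i].is_decoy))
    q_at: dict[int, float] = {}
    n_decoy = n_target = 0
    fdrs: list[float] = []
    for i in order:
        if psms[i].is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    # ties share the worst FDR among equal scores before the running minimum
    for k in range(len(order) - 2, -1, -1):
        if psms[order[k]].score == psms[order[k + 1]].score:
            fdrs[k] = max(fdrs[k], fdrs[k + 1])
    running = float("inf")
    for k in range(len(order) - 1, -1, -1):
        running = min(running, fdrs[k])
        q_at[order[k]] = min(running, 1.0)
    return [replace(p, q_value=q_at[i]) for i, p in enumerate(psms)]


def filter_at_fdr(psms: list[PSM], threshold: float = FDR_THRESHOLD) -> list[PSM]:
    return [p for p in psms if not p.is_decoy and p.q_value <= threshold]


def annotate_site_support(psms: list[PSM], strict: bool = False) -> list[PSM]:
    out = []
    for p in psms:
        if p.peptide.is_mutant and p.peptide.mut_offset_in_peptide is not None:
            out.append(replace(p, site_supported=site_supported(p, strict)))
        else:
            out.append(p)
    return out


def write_psm_table(psms: list[PSM], path) -> None:
    from pathlib import Path

    lines = ["spectrum\tpeptide\tmods\tparent\tscore\tq_value\tis_decoy\t"
             "is_mutant\tsite_supported\tmatched_ions"]
    for p in psms:
        ions = ";".join(f"{m.series}{m.index}^{m.charge}" for m in p.matched)
        mods = ";".join(f"{pos}:{delta:+.5f}" for pos, delta in p.peptide.modifications)
        lines.append(
            f"{p.spectrum_id}\t{p.peptide.sequence}\t{mods}\t{p.peptide.parent_id}\t"
            f"{p.score:.4f}\t{p.q_value:.6g}\t{int(p.is_decoy)}\t"
            f"{int(p.peptide.is_mutant)}\t{int(p.site_supported)}\t{ions}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def coverage_matrix(psm: PSM) -> str:
    """Text rendering of the matched b/y ladder for one PSM (validation view)."""
    seq = psm.peptide.sequence
    n = len(seq)
    matched = {(m.series, m.index) for m in psm.matched}
    b_row = "".join("b" if ("b", i) in matched else "." for i in range(1, n))
    y_row = "".join("y" if ("y", n - i) in matched else "." for i in range(1, n))
    return f"  {seq}\nb {b_row}-\ny {y_row}-"
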