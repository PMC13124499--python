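"""Personalized mutant-protein database construction.

Missense entries are the substituted residue with up to 25 reference
residues on each side (truncated at protein termini). Frameshift entries
are the last 24 unaffected reference residues followed by the shifted-frame
translation up to (excluding) the first stop codon. Targets are the
reference proteome plus mutant entries; decoys are full-sequence reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .variants import VariantCall

MISSENSE_FLANK = 25
FRAMESHIFT_PREFIX = 24
DECOY_PREFIX = "rev_"

_STOP = "*"
_VALID_BASES = set("ACGTU")


class CdsError(ValueError):
    """Bad coding sequence or coordinate."""


class EntryError(ValueError):
    """Variant cannot be turned into a database entry."""


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate ``cds`` with the standard codon table up to the first stop.

    Returns ``(protein, stop_found)``; trailing bases short of a full codon
    are ignored.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise CdsError(f"CDS shorter than one codon: {len(cds)} nt")
    bad = set(cds) - set("ACGT")
    if bad:
        raise CdsError(f"non-ACGT/U character(s) {sorted(bad)} in CDS")
    trimmed = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(trimmed).translate(table=1))
    stop_idx = aa.find(_STOP)
    if stop_idx == -1:
        return aa, False
    return aa[:stop_idx], True


@dataclass(frozen=True)
class MutantEntry:
    entry_id: str
    source_accession: str
    gene: str
    hgvs_p: str
    kind: str  # "missense" | "frameshift"
    sequence: str
    mut_offset: int       # 1-based offset of first mutation-affected residue
    left_flank: int
    right_flank: int
    start_in_protein: int  # 1-based coordinate of sequence[0] in source protein
    stop_found: bool = True          # frameshift: downstream stop codon present
    coincident_ref: bool = False     # neo-frame residue equals reference continuation


def build_missense_entry(
    protein: str,
    protein_pos: int,
    alt_aa: str,
    accession: str = "",
    gene: str = "",
    flank: int = MISSENSE_FLANK,
) -> MutantEntry:
    length = len(protein)
    if not 1 <= protein_pos <= length:
        raise EntryError(f"protein_pos {protein_pos} outside 1..{length}")
    ref_aa = protein[protein_pos - 1]
    if ref_aa == alt_aa:
        raise EntryError(f"synonymous call at {protein_pos}: {ref_aa}->{alt_aa}")
    if alt_aa == _STOP or alt_aa not in set("ACDEFGHIKLMNPQRSTVWY"):
        raise EntryError(f"alt residue {alt_aa!r} outside canonical alphabet")
    left = min(flank, protein_pos - 1)
    right = min(flank, length - protein_pos)
    start = protein_pos - left
    window = protein[start - 1 : protein_pos + right]
    sequence = window[:left] + alt_aa + window[left + 1 :]
    hgvs = f"p.{ref_aa}{protein_pos}{alt_aa}"
    return MutantEntry(
        entry_id=f"mut|{accession}|{gene}_{hgvs}",
        source_accession=accession,
        gene=gene,
        hgvs_p=hgvs,
        kind="missense",
        sequence=sequence,
        mut_offset=left + 1,
        left_flank=left,
        right_flank=right,
        start_in_protein=start,
    )


def build_frameshift_entry(
    cds: str,
    cds_pos: int,
    inserted: str = "",
    deleted: int = 0,
    accession: str = "",
    gene: str = "",
    prefix_len: int = FRAMESHIFT_PREFIX,
) -> MutantEntry:
    """Apply an out-of-frame indel at 1-based ``cds_pos`` and build the entry.

    A deletion removes ``deleted`` bases starting at ``cds_pos``; an
    insertion places ``inserted`` immediately before ``cds_pos``.
    """
    cds = cds.upper().replace("U", "T")
    if not 1 <= cds_pos <= len(cds):
        raise CdsError(f"cds_pos {cds_pos} outside 1..{len(cds)}")
    net = len(inserted) - deleted
    if net == 0 or net % 3 == 0:
        raise EntryError(f"indel of net length {net} is in-frame, not a frameshift")
    if inserted and deleted:
        raise EntryError("specify an insertion or a deletion, not both")

    reference, _ = translate_cds(cds)
    i = cds_pos - 1
    mutated = cds[:i] + inserted + cds[i + deleted :]
    affected_codon = i // 3  # 0-based index of first codon containing a change

    prefix_start = max(0, affected_codon - prefix_len)
    ref_prefix = reference[prefix_start:affected_codon]
    neo, stop_found = translate_cds(mutated[affected_codon * 3 :]) if len(
        mutated
    ) - affected_codon * 3 >= 3 else ("", False)
    sequence = ref_prefix + neo
    if not sequence:
        raise EntryError("frameshift entry is empty (indel at transcript edge)")

    # flag the (legitimate) coincidence where the first shifted residue
    # reproduces the reference continuation
    coincident = bool(neo) and affected_codon < len(reference) and (
        neo[0] == reference[affected_codon]
    )
    mut_offset = len(ref_prefix) + 1
    hgvs = f"p.X{affected_codon + 1}fs"
    return MutantEntry(
        entry_id=f"mut|{accession}|{gene}_{hgvs}",
        source_accession=accession,
        gene=gene,
        hgvs_p=hgvs,
        kind="frameshift",
        sequence=sequence,
        mut_offset=mut_offset,
        left_flank=len(ref_prefix),
        right_flank=0,
        start_in_protein=prefix_start + 1,
        stop_found=stop_found,
        coincident_ref=coincident,
    )


def build_entry(
    variant: VariantCall,
    proteins: dict[str, str],
    cds: dict[str, str] | None = None,
    genes: dict[str, str] | None = None,
) -> MutantEntry:
    """Build the database entry for one filtered variant.

    Missense calls carrying a CDS coordinate are cross-checked: the mutated
    codon must translate to the stated alt residue.
    """
    if variant.accession not in proteins:
        raise EntryError(f"unknown accession {variant.accession!r}")
    protein = proteins[variant.accession]
    gene = (genes or {}).get(variant.accession, variant.gene)
    if variant.type == "missense":
        if variant.alt_aa is None:
            raise EntryError(f"{variant.key}: missense call without alt_aa")
        if cds and variant.accession in cds and variant.cds_pos:
            _check_missense_consistency(variant, cds[variant.accession])
        return build_missense_entry(
            protein, variant.protein_pos, variant.alt_aa,
            accession=variant.accession, gene=gene,
        )
    if cds is None or variant.accession not in cds:
        raise EntryError(f"{variant.key}: frameshift call requires the CDS")
    deleted = max(0, len(variant.ref_base) - len(variant.alt_base))
    inserted = variant.alt_base[len(variant.ref_base):] if len(variant.alt_base) > len(variant.ref_base) else ""
    # VCF-style anchored alleles: the change starts after the shared anchor base
    pos = variant.cds_pos + min(len(variant.ref_base), len(variant.alt_base))
    return build_frameshift_entry(
        cds[variant.accession], pos, inserted=inserted, deleted=deleted,
        accession=variant.accession, gene=gene,
    )


def _check_missense_consistency(variant: VariantCall, cds_seq: str) -> None:
    codon_idx = (variant.cds_pos - 1) // 3
    if codon_idx + 1 != variant.protein_pos:
        raise EntryError(
            f"{variant.key}: cds_pos {variant.cds_pos} maps to codon "
            f"{codon_idx + 1}, not protein_pos {variant.protein_pos}"
        )
    codon = list(cds_seq[codon_idx * 3 : codon_idx * 3 + 3])
    codon[(variant.cds_pos - 1) % 3] = variant.alt_base
    translated = str(Seq("".join(codon)).translate(table=1))
    if translated != variant.alt_aa:
        raise EntryError(
            f"{variant.key}: mutated codon translates to {translated!r}, "
            f"stated alt residue is {variant.alt_aa!r}"
        )


@dataclass(frozen=True)
class DatabaseRecord:
    record_id: str
    sequence: str
    is_decoy: bool
    is_mutant: bool
    entry: MutantEntry | None = None


@dataclass
class PersonalizedDatabase:
    targets: list[DatabaseRecord]
    decoys: list[DatabaseRecord]
    provenance: dict

    @property
    def records(self) -> list[DatabaseRecord]:
        return self.targets + self.decoys

    @property
    def mutant_entries(self) -> list[MutantEntry]:
        return [r.entry for r in self.targets if r.entry is not None]


def assemble_personalized_db(
    reference: list[tuple[str, str]],
    entries: list[MutantEntry],
    patient_id: str = "",
    provenance: dict | None = None,
) -> PersonalizedDatabase:
    """Combine reference proteome and mutant entries; append reversed decoys.

    Duplicate mutant sequences are collapsed, keeping every source in the
    provenance map. Ordering is deterministic: reference order, then entries
    sorted by (accession, start position, id).
    """
    known = {acc for acc, _ in reference}
    for e in entries:
        if e.source_accession not in known:
            raise EntryError(f"entry {e.entry_id} references unknown accession "
                             f"{e.source_accession!r}")
    targets = [
        DatabaseRecord(record_id=acc, sequence=seq, is_decoy=False, is_mutant=False)
        for acc, seq in reference
    ]
    dedup: dict[str, MutantEntry] = {}
    sources: dict[str, list[str]] = {}
    for e in sorted(entries, key=lambda e: (e.source_accession, e.start_in_protein, e.entry_id)):
        if e.sequence in dedup:
            sources[e.sequence].append(e.entry_id)
        else:
            dedup[e.sequence] = e
            sources[e.sequence] = [e.entry_id]
    for seq, e in dedup.items():
        header = f"{e.entry_id}|start={e.start_in_protein}"
        targets.append(
            DatabaseRecord(record_id=header, sequence=seq, is_decoy=False,
                           is_mutant=True, entry=e)
        )
    ids = [t.record_id for t in targets]
    if len(set(ids)) != len(ids):
        raise EntryError("duplicate record ids in assembled database")
    db = PersonalizedDatabase(
        targets=targets,
        decoys=[],
        provenance={
            "patient_id": patient_id,
            "duplicate_sources": {
                dedup[s].entry_id: srcs for s, srcs in sources.items() if len(srcs) > 1
            },
            **(provenance or {}),
        },
    )
    db.decoys = generate_decoys(db)
    return db


def generate_decoys(db: PersonalizedDatabase) -> list[DatabaseRecord]:
    """One full-sequence-reversed decoy per target, ids prefixed rev_."""
    decoys = []
    palindromes = []
    for t in db.targets:
        rev = t.sequence[::-1]
        if rev == t.sequence:
            palindromes.append(t.record_id)
        decoys.append(
            DatabaseRecord(
                record_id=DECOY_PREFIX + t.record_id,
                sequence=rev,
                is_decoy=True,
                is_mutant=t.is_mutant,
                entry=t.entry,
            )
        )
    if palindromes:
        db.provenance.setdefault("palindromic_targets", []).extend(palindromes)
    return decoys


# --- FASTA I/O -------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_database_fasta(db: PersonalizedDatabase, path: str | Path,
                         decoy_path: str | Path | None = None) -> None:
    """Write targets+decoys to one FASTA, or decoys separately if asked."""
    targets = [(r.record_id, r.sequence) for r in db.targets]
    decoys = [(r.record_id, r.sequence) for r in db.decoys]
    if decoy_path is None:
        write_fasta(targets + decoys, path)
    else:
        write_fasta(targets, path)
        write_fasta(decoys, decoy_path)


def write_entry_manifest(entries: list[MutantEntry], path: str | Path) -> None:
    lines = ["entry_id\tkind\thgvs_p\tmut_offset\tleft_flank\tright_flank\tstart_in_protein"]
    for e in entries:
        lines.append(
            f"{e.entry_id}\t{e.kind}\t{e.hgvs_p}\t{e.mut_offset}\t"
            f"{e.left_flank}\t{e.right_flank}\t{e.start_in_protein}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
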