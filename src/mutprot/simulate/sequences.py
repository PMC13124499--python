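"""Reference proteome/CDS generation by reverse translation.

Each protein is drawn residue-by-residue and its CDS is built by picking a
random codon per residue plus a stop codon, so translate(CDS) == protein
holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = tuple(standard_dna_table.stop_codons)

#: codons per residue, from the standard table
CODONS_FOR: dict[str, tuple[str, ...]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    CODONS_FOR.setdefault(aa, tuple())
    CODONS_FOR[aa] = CODONS_FOR[aa] + (codon,)


@dataclass(frozen=True)
class SyntheticProteinSet:
    proteins: tuple[tuple[str, str, str], ...]  # (accession, gene, sequence)
    cds: tuple[tuple[str, str], ...]            # (accession, nucleotide sequence)

    def protein_map(self) -> dict[str, str]:
        return {acc: seq for acc, _gene, seq in self.proteins}

    def cds_map(self) -> dict[str, str]:
        return dict(self.cds)

    def gene_map(self) -> dict[str, str]:
        return {acc: gene for acc, gene, _seq in self.proteins}


def generate_reference_set(config) -> SyntheticProteinSet:
    rng = config.rng("sequences")
    proteins = []
    cds_list = []
    # mildly K/R-enriched composition so tryptic peptides of searchable
    # length are plentiful
    weights = np.array([3.0 if aa in "KR" else 1.0 for aa in AMINO_ACIDS])
    weights /= weights.sum()
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:04d}"
        gene = f"GENE{i + 1}"
        length = int(rng.integers(config.min_protein_len, config.max_protein_len + 1))
        residues = rng.choice(list(AMINO_ACIDS), size=length, p=weights)
        protein = "".join(residues)
        codons = [
            CODONS_FOR[aa][rng.integers(len(CODONS_FOR[aa]))] for aa in protein
        ]
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        proteins.append((acc, gene, protein))
        cds_list.append((acc, "".join(codons)))
    return SyntheticProteinSet(proteins=tuple(proteins), cds=tuple(cds_list))
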