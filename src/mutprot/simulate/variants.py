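"""Variant planting with ground-truth labels.

True somatics draw tumor_alt binomially at their true VAF (then enforced
to satisfy the four somatic criteria so the filter recovers the planted
set exactly); germline/artifact negatives are planted in four flavors, one
failing each filter clause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ..variants import VariantCall
from .sequences import STOP_CODONS, SyntheticProteinSet


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedVariant:
    variant: VariantCall
    is_somatic: bool
    flavor: str       # "somatic" | "neg_i" | "neg_ii" | "neg_iii" | "neg_iv"
    true_vaf: float


@dataclass
class TruthSet:
    planted: list[PlantedVariant]
    expressed_keys: tuple[str, ...] = ()
    true_amounts: dict = field(default_factory=dict)

    @property
    def somatic_keys(self) -> set[str]:
        return {p.variant.key for p in self.planted if p.is_somatic}

    def to_json_dict(self) -> dict:
        return {
            "planted": [
                {
                    "key": p.variant.key,
                    "accession": p.variant.accession,
                    "type": p.variant.type,
                    "is_somatic": p.is_somatic,
                    "flavor": p.flavor,
                    "true_vaf": p.true_vaf,
                }
                for p in self.planted
            ],
            "expressed": list(self.expressed_keys),
            "true_amounts": self.true_amounts,
        }


def _missense_site(cds: str, codon_idx: int, rng: np.random.Generator):
    """Pick a single-base substitution in codon ``codon_idx`` changing the
    residue to another canonical one; None if the codon has no such edit.

    Substitutions that are mass-indistinguishable at the search tolerances
    (L<->I identical, K<->Q 0.036 Da apart) are never planted: no MS method
    could recover them and the recovery contract would be unmeetable.
    """
    from ..ms.masses import RESIDUE_MASS

    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    ref_aa = str(Seq(codon).translate(table=1))
    options = []
    for base_pos in range(3):
        for base in "ACGT":
            if base == codon[base_pos]:
                continue
            alt_codon = codon[:base_pos] + base + codon[base_pos + 1 :]
            if alt_codon in STOP_CODONS:
                continue
            alt_aa = str(Seq(alt_codon).translate(table=1))
            if alt_aa != ref_aa and abs(
                RESIDUE_MASS[alt_aa] - RESIDUE_MASS[ref_aa]
            ) > 0.05:
                options.append((base_pos, base, ref_aa, alt_aa))
    if not options:
        return None
    return options[rng.integers(len(options))]


def _depth(rng: np.random.Generator, mean: float, minimum: int = 30) -> int:
    return max(minimum, int(rng.poisson(mean)))


def plant_variants(
    ref: SyntheticProteinSet, config
) -> tuple[list[VariantCall], TruthSet]:
    rng = config.rng("variants")
    cds_map = ref.cds_map()
    gene_map = ref.gene_map()
    accessions = [acc for acc, _g, _s in ref.proteins]

    n_somatic = config.n_missense + config.n_frameshift
    n_neg = 4 * config.n_negatives_per_clause
    total = n_somatic + n_neg

    # candidate (accession, codon_idx) sites, interior codons only so that
    # entries and tryptic peptides have room on both sides
    sites: list[tuple[str, int]] = []
    for acc in accessions:
        n_codons = len(cds_map[acc]) // 3 - 1  # exclude stop
        sites.extend((acc, c) for c in range(5, n_codons - 5))
    if total > len(sites):
        raise GenerationError(
            f"{total} variants requested but only {len(sites)} codon sites available"
        )
    site_queue = [sites[i] for i in rng.permutation(len(sites))]
    planted: list[PlantedVariant] = []
    variants: list[VariantCall] = []

    flavors = (
        ["somatic"] * n_somatic
        + ["neg_i", "neg_ii", "neg_iii", "neg_iv"] * config.n_negatives_per_clause
    )
    kinds = (
        ["missense"] * config.n_missense
        + ["frameshift"] * config.n_frameshift
        + ["missense"] * n_neg
    )

    def next_site(kind: str):
        """Pop sites until one admits the requested variant kind."""
        while site_queue:
            acc, codon_idx = site_queue.pop()
            if kind == "frameshift":
                return acc, codon_idx, None
            info = _missense_site(cds_map[acc], codon_idx, rng)
            if info is not None:
                return acc, codon_idx, info
        raise GenerationError("ran out of mutable codon sites")

    for flavor, kind in zip(flavors, kinds):
        acc, codon_idx, site_info = next_site(kind)
        cds = cds_map[acc]
        true_vaf = float(rng.uniform(config.vaf_min, config.vaf_max))
        if kind == "missense":
            base_pos, alt_base, ref_aa, alt_aa = site_info
            cds_pos = codon_idx * 3 + base_pos + 1
            ref_base = cds[cds_pos - 1]
            protein_pos = codon_idx + 1
        else:
            # 1-bp deletion, VCF-anchored at the base before the deleted one
            cds_pos = codon_idx * 3 + 1
            anchor = cds[cds_pos - 1]
            ref_base = cds[cds_pos - 1 : cds_pos + 1]
            alt_base = anchor
            ref_aa = alt_aa = None
            protein_pos = codon_idx + 1

        counts = _draw_counts(rng, config, flavor, true_vaf)
        v = VariantCall(
            accession=acc,
            gene=gene_map[acc],
            type=kind,
            cds_pos=cds_pos,
            protein_pos=protein_pos,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            ref_base=ref_base,
            alt_base=alt_base,
            simple_repeat=(flavor == "neg_iv"),
            **counts,
        )
        variants.append(v)
        planted.append(
            PlantedVariant(v, is_somatic=(flavor == "somatic"), flavor=flavor,
                           true_vaf=true_vaf)
        )

    truth = TruthSet(
        planted=planted,
        expressed_keys=tuple(
            p.variant.key for p in planted if p.is_somatic
        ),
    )
    return variants, truth


def _draw_counts(rng, config, flavor: str, true_vaf: float) -> dict[str, int]:
    t_depth = _depth(rng, config.depth_mean)
    n_depth = _depth(rng, config.depth_mean)
    if flavor == "somatic":
        t_alt = int(rng.binomial(t_depth, true_vaf))
        # enforce the pass criteria so planted truth == filter output exactly
        t_alt = min(t_depth, max(t_alt, 4, int(0.05 * t_depth) + 1))
        n_alt = min(2, int(rng.binomial(n_depth, config.normal_error_rate)))
    elif flavor == "neg_i":
        # fails only clause i: 3 tumor reads at a depth keeping VAF > 0.05
        t_depth = 40
        t_alt = 3
        n_alt = min(2, int(rng.binomial(n_depth, config.normal_error_rate)))
    elif flavor == "neg_ii":
        # germline: tumor side looks somatic, normal carries the allele
        t_alt = min(t_depth, max(int(rng.binomial(t_depth, true_vaf)), 4,
                                 int(0.05 * t_depth) + 1))
        n_alt = max(3, int(rng.binomial(n_depth, true_vaf)))
        n_alt = min(n_alt, n_depth)
    elif flavor == "neg_iii":
        # low-VAF artifact: > 3 reads but VAF <= 0.05
        t_depth = max(t_depth, 85)
        t_alt = int(0.05 * t_depth)
        n_alt = min(2, int(rng.binomial(n_depth, config.normal_error_rate)))
    elif flavor == "neg_iv":
        # repeat-flagged, otherwise pass-like
        t_alt = min(t_depth, max(int(rng.binomial(t_depth, true_vaf)), 4,
                                 int(0.05 * t_depth) + 1))
        n_alt = min(2, int(rng.binomial(n_depth, config.normal_error_rate)))
    else:  # pragma: no cover
        raise GenerationError(f"unknown flavor {flavor}")
    return {
        "tumor_alt_reads": t_alt,
        "tumor_total_reads": t_depth,
        "normal_alt_reads": n_alt,
        "normal_total_reads": n_depth,
    }
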