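"""End-to-end orchestration, cohort statistics and landscape reporting."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ms.digest import Peptide
from .ms.search import (
    FDR_THRESHOLD,
    annotate_site_support,
    estimate_qvalues,
    filter_at_fdr,
    search,
)
from .mutantdb import MutantEntry, assemble_personalized_db, build_entry
from .variants import FilterResult, VariantCall, apply_somatic_filters

log = logging.getLogger("mutprot.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SampleReport:
    sample_id: str
    n_variants_in: int
    n_variants_pass: int
    n_entries: int
    n_spectra: int
    n_psms: int
    n_psms_accepted: int
    n_mutant_psms_accepted: int
    detected_mutations: tuple[str, ...]   # entry keys passing FDR + site support
    unidentified: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_mutant_psms_accepted <= self.n_psms_accepted <= self.n_psms
        assert self.n_variants_pass <= self.n_variants_in
        assert self.n_entries <= self.n_variants_pass

    def to_json(self) -> str:
        d = asdict(self)
        d["detected_mutations"] = sorted(self.detected_mutations)
        return json.dumps(d, indent=2, sort_keys=True, default=str)


def map_mutation_coordinates(
    entry: MutantEntry, peptide: Peptide
) -> tuple[tuple[int, int], int]:
    """Peptide span in the source protein (1-based inclusive) and the
    protein coordinate of the mutated residue."""
    if peptide.mut_offset_in_peptide is None or not peptide.is_mutant:
        raise ValueError("peptide does not carry mutation evidence")
    span_start = entry.start_in_protein + peptide.start_offset - 1
    span_end = span_start + len(peptide.sequence) - 1
    mut_pos = span_start + peptide.mut_offset_in_peptide - 1
    return (span_start, span_end), mut_pos


def vaf_detection_association(
    filter_results: list[FilterResult],
    detected_keys: set[str],
) -> dict:
    """Rank-sum comparison of tumor VAF: protein-detected vs non-detected."""
    detected = [r.vaf_tumor for r in filter_results if r.variant.key in detected_keys]
    undetected = [r.vaf_tumor for r in filter_results if r.variant.key not in detected_keys]
    out = {"n_detected": len(detected), "n_undetected": len(undetected),
           "statistic": None, "p_value": None, "computable": False}
    if len(detected) >= 2 and len(undetected) >= 2:
        stat, p = stats.mannwhitneyu(detected, undetected, alternative="two-sided")
        out.update(statistic=float(stat), p_value=float(p), computable=True)
    return out


def render_landscape(
    reports: dict[str, "SampleReport"],
    path: str | Path | None = None,
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Mutation x specimen detection-flag matrix (Fig-style overview).

    Keys of ``reports`` are specimen labels; rows are all mutations detected
    in at least one specimen plus any listed under extras['candidates'].
    """
    if not reports:
        raise ValueError("need >= 1 report")
    mutations: set[str] = set()
    for rep in reports.values():
        mutations |= set(rep.detected_mutations)
        mutations |= set(rep.extras.get("candidates", ()))
    rows = sorted(mutations)
    data = {
        specimen: [m in rep.detected_mutations for m in rows]
        for specimen, rep in sorted(reports.items())
    }
    df = pd.DataFrame(data, index=rows)
    if path is not None:
        df.astype(int).to_csv(path, sep="\t", index_label="mutation")
    if image_path is not None:
        _plot_landscape(df, image_path)
    return df


def _plot_landscape(df: pd.DataFrame, image_path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * max(1, len(df.columns)), 1 + 0.3 * max(1, len(df)))
    )
    ax.imshow(df.values.astype(float), cmap="YlOrBr", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(df)), df.index, fontsize=6)
    ax.set_title("Mutant-protein detection landscape")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)


def run_stages(
    sample_id: str,
    variants: list[VariantCall],
    reference: list[tuple[str, str]],
    cds: dict[str, str],
    spectra,
    genes: dict[str, str] | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    strict_site: bool = False,
    search_kwargs: dict | None = None,
) -> tuple[SampleReport, list, list[FilterResult]]:
    """filter -> build-db -> search -> FDR/site validation; returns the
    report, accepted PSMs and per-variant filter results."""
    log.info("stage=filter sample=%s n_in=%d", sample_id, len(variants))
    results = apply_somatic_filters(variants)
    passing = [r.variant for r in results if r.passed]
    log.info("stage=filter n_pass=%d", len(passing))

    entries: list[MutantEntry] = []
    proteins = dict(reference)
    skipped: list[str] = []
    for v in passing:
        try:
            entries.append(build_entry(v, proteins, cds, genes))
        except Exception as exc:  # entry-level rejects are reported, not fatal
            skipped.append(f"{v.key}: {exc}")
    log.info("stage=build-db n_entries=%d n_skipped=%d", len(entries), len(skipped))

    try:
        db = assemble_personalized_db(reference, entries, patient_id=sample_id)
    except Exception as exc:
        raise PipelineError("build-db", str(exc)) from exc

    log.info("stage=search n_spectra=%d n_targets=%d", len(spectra), len(db.targets))
    psms, unidentified = search(spectra, db, **(search_kwargs or {}))
    psms = estimate_qvalues(psms)
    psms = annotate_site_support(psms, strict=strict_site)
    accepted = filter_at_fdr(psms, fdr_threshold)
    mutant_accepted = [p for p in accepted
                       if p.peptide.is_mutant and p.site_supported]
    detected = sorted({_entry_key(p.peptide.parent_id) for p in mutant_accepted})
    log.info("stage=fdr n_psms=%d n_accepted=%d n_mutant=%d",
             len(psms), len(accepted), len(mutant_accepted))

    report = SampleReport(
        sample_id=sample_id,
        n_variants_in=len(variants),
        n_variants_pass=len(passing),
        n_entries=len(entries),
        n_spectra=len(spectra),
        n_psms=len(psms),
        n_psms_accepted=len(accepted),
        n_mutant_psms_accepted=len(mutant_accepted),
        detected_mutations=tuple(detected),
        unidentified=tuple(unidentified),
        extras={"skipped_entries": skipped,
                "candidates": sorted(_entry_key(e.entry_id) for e in entries)},
    )
    return report, accepted, results


def _entry_key(entry_id: str) -> str:
    """mut|ACC|GENE_p.X123Y[|start=..] -> ACC:p.X123Y (matches VariantCall.key)."""
    parts = entry_id.split("|")
    if len(parts) >= 3 and parts[0] == "mut":
        acc = parts[1]
        hgvs = parts[2].rsplit("_", 1)[-1]
        return f"{acc}:{hgvs}"
    return entry_id


def run_synthetic(sim_config, fdr_threshold: float = FDR_THRESHOLD,
                  strict_site: bool = False) -> dict:
    """Generate a full synthetic sample and run every identification stage.

    Returns a dict with the report, truth set, filter results and PSMs —
    the programmatic equivalent of the CLI `run` subcommand.
    """
    from .simulate import (
        generate_reference_set,
        plant_variants,
        simulate_sample_spectra,
    )

    ref = generate_reference_set(sim_config)
    variants, truth = plant_variants(ref, sim_config)
    reference = [(acc, seq) for acc, _g, seq in ref.proteins]
    results = apply_somatic_filters(variants)
    proteins = ref.protein_map()
    cds = ref.cds_map()
    genes = ref.gene_map()
    expressed = set(truth.expressed_keys)
    # spectra exist only for protein-expressed mutations; the database still
    # carries entries for every passing variant (built inside run_stages)
    expressed_entries = [
        build_entry(r.variant, proteins, cds, genes)
        for r in results if r.passed and r.variant.key in expressed
    ]
    spectra, spec_truth = simulate_sample_spectra(
        expressed_entries, reference, sim_config)
    report, accepted, results = run_stages(
        sample_id=f"sim-seed{sim_config.seed}",
        variants=variants,
        reference=reference,
        cds=cds,
        spectra=spectra,
        genes=genes,
        fdr_threshold=fdr_threshold,
        strict_site=strict_site,
    )
    return {
        "report": report,
        "truth": truth,
        "spectrum_truth": spec_truth,
        "filter_results": results,
        "accepted_psms": accepted,
        "reference": ref,
    }
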