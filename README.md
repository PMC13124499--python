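# mutprot

Personalized proteogenomic detection and absolute quantification of somatic
mutant proteins, built as a tested, reusable pipeline exercised end-to-end on
synthetic data.

The pipeline covers:

1. **Somatic variant filtering** (`mutprot.variants`) — the four-clause
   filter: tumor variant reads > 3, normal variant reads < 3, tumor VAF >
   0.05, not in a simple repeat (all comparisons strict; boundary values
   fail). TSV and minimal-VCF (AD counts in TUMOR/NORMAL columns) readers.
2. **Personalized mutant-protein database** (`mutprot.mutantdb`) — missense
   entries are the substituted residue with up to 25 reference residues per
   side; frameshift entries are the last 24 reference residues followed by
   the shifted-frame translation up to the first stop codon. Entries are
   merged with the reference proteome and full-sequence-reversed decoys.
3. **In-silico MS/MS search** (`mutprot.ms`) — Trypsin/LysC digestion (cleave
   after K always, after R except before P, ≤ 2 missed cleavages, length
   6–30), monoisotopic b/y fragment theory with carbamidomethyl-C static and
   Met-oxidation variable (≤ 4), 10 ppm precursor / 0.6 Da fragment
   tolerances, charges 2–5, an in-house matched-count + cosine scorer,
   target-decoy q-values filtered at 0.01, and mutation-site validation via
   site-determining ions. MGF I/O included.
4. **PRM absolute quantification** (`mutprot.prm`) — peak detection
   (heavy-standard-anchored), trapezoidal AUC with baseline subtraction,
   amount = spike × AUC_light / AUC_heavy, co-elution checks, mean ± SE
   summaries over transitions, and the paired pre/post t-test. Heavy-label
   mass shifts are computed from configurable ¹³C/¹⁵N counts.
5. **Synthetic data** (`mutprot.simulate`) — reverse-translated
   proteome/CDS pairs, variant planting with per-clause negative controls
   and ground-truth labels, b/y spectra with dropout/jitter/noise, Gaussian
   light/heavy chromatogram pairs, and longitudinal pre/post series. All
   generators are deterministic per seed with partitioned random streams.
6. **Orchestration** (`mutprot.pipeline`, `mutprot.cli`) — end-to-end runs,
   coordinate bookkeeping back to protein space, VAF-vs-detection rank-sum
   association, and detection-landscape reports.

## CLI

```bash
mutprot simulate --seed 1 --out runs/sim          # synthetic FASTA/TSV/MGF/CSV
mutprot filter-variants --in runs/sim/variants.tsv --out filtered.tsv
mutprot build-db --reference runs/sim/proteome.fasta --cds runs/sim/cds.fasta \
    --variants runs/sim/variants.tsv --out db.fasta --manifest manifest.tsv
mutprot digest --fasta runs/sim/proteome.fasta --out peptides.tsv
mutprot search --mgf runs/sim/spectra.mgf --reference runs/sim/proteome.fasta \
    --cds runs/sim/cds.fasta --variants runs/sim/variants.tsv --out psms.tsv
mutprot quant --chromatograms runs/sim/chromatograms.csv --out quant.tsv
mutprot run --seed 1 --out runs/full              # full synthetic end-to-end
mutprot report --reports runs/full/report.json --out landscape.tsv
```

`simulate` accepts a YAML config (`--config`) mirroring
`mutprot.simulate.SimulationConfig`; `--seed` overrides the config seed.

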