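# Methods

## Bovine-anchored numbering

Opsin tuning sites are reported in bovine rhodopsin coordinates. Queries are
globally aligned to the packaged 348-aa bovine anchor (UniProt P02699, the
chain of PDB 1U19) with Biopython's `PairwiseAligner`: BLOSUM62, affine gaps
(open 10, extend 1). No convention exists for the exact parameters; any
reasonable global aligner must reproduce the canonical site residues for
true opsins, and the round-trip tests (random indel scripts away from the
sites) verify exactly that. Among co-optimal alignments the aligner's first
deterministic traceback is used, so extraction is reproducible. Queries
shorter than 50 residues are rejected — too little signal to establish
homologous numbering. Ambiguity codes B/Z/J are scored as X during alignment
and normalized to AMBIGUOUS at extraction; sites aligned to gaps are
MISSING, never silently imputed.

## λ_max estimation

The estimator mirrors how comparative opsin studies assign λ_max without
expressing every protein: rank a panel of reference pigments by tuning-site
mismatch count (ties: damselfish references first, then in-vitro before MSP,
then lexicographic id — a total order, so panel file order never matters),
then add the tabulated shift of each separating substitution to the
reference λ_max, flipping sign for the reverse direction.

Numerical choices and defaults:

- **Site-effect table** (`data/site_effects.tsv`): A118S = +5 nm (an
  empirically established shift). A114S = +5 nm is a package default, not an
  empirical value: it reproduces the observed ~10 nm joint short↔long shift
  and falls inside the 3–9 nm single-site interval reported for the Chromis
  duplicates. Both entries are config-overridable.
- **Reference panel** (`data/reference_panel.tsv`): λ_max values here are
  defaults consistent with the published damselfish class ranges (short
  356–362 nm with A114/A118, long 368–370 nm with S114/S118), with
  provenance strings naming the kinds of sources a curated panel would cite;
  replace with curated values for quantitative use on real data. Non-focal
  sites carry a package SWS1 consensus so that mismatch counting behaves.
- **Homology threshold** (default 0): single-site effects in SWS1 are
  usually not additive, so a mismatch without a tabulated effect makes the
  estimate UNDETERMINED rather than being skipped. Raising the threshold
  admits estimates while counting the unmatched sites in the audit output.
- **Ambiguity**: any AMBIGUOUS tuning site → UNDETERMINED, with the reason
  recorded (mirrors the exclusion of sequences with ambiguous positions).
- **Site 125**: extracted and polarity-flagged (S↔A is a polarity shift) but
  excluded from matching and λ arithmetic — it is a putative tuning site
  awaiting empirical confirmation.
- **Classes**: short [356, 362] and long [368, 370] are inclusive at their
  printed endpoints; (362, 368) is intermediate; anything else is
  unclassified, never coerced. The chromophore is fixed to A1 (marine
  fishes); no A2 conversion is implemented.

## Ancestral reconstruction

Both routes are implemented because the original reconstructions do not
state their model, and the "intermediate ancestor" claim should not hinge on
one algorithm:

- **Parsimony**: Hartigan's generalization of Fitch (correct on
  multifurcations). The concrete labelling keeps the parent state when it is
  in a node's candidate set and otherwise takes the lexicographic minimum;
  the root takes the lexicographic minimum of its set. Counts and labellings
  are validated against brute-force enumeration on random ≤7-tip trees.
- **Marginal ML**: equal-rates Mk with k = observed states (plus configured
  extras), uniform root prior, branch lengths as given (default 1.0 when
  absent, in expected substitutions). Posteriors come from the inside
  (pruning) pass combined with an outside pass and are validated against
  brute-force summation to 1e-8. Reported state = argmax with lexicographic
  tie-break at ties within 1e-12.
- **Masking**: tip states can be set to missing and marginalized (the
  control in which reference species' 114/118 residues are removed).

**Gain events**: Sankoff small parsimony over {absent, present} with
configurable costs (default 1/1; the duplication analysis also runs gain=2,
loss=1 since transcriptome absence may be expression failure rather than
loss). Ties prefer absent, which (a) makes an ancestrally absent root the
default and (b) pushes gains tipward, the conservative reading for
duplication counting. Gains and losses are read off the reported labelling,
so gains·gain_cost + losses·loss_cost always equals the optimum cost.

The curated copy-number matrix (`uvopsin.datasets`) encodes the genome
survey: two-copy *Chromis chromis*, eleven two-copy anemonefish species,
two-copy *Pomacentrus amboinensis*/*australis*, single-copy *Stegastes
partitus*, *Dascyllus trimaculatus* and *Acanthochromis polyacanthus*, on
the subfamily topology. The protein-tree fixture for the ancestral check is
synthetic (the published tree is not redistributed): short AA Stegastinae
and Abudefdufinae, long SS Chrominae, mixed Pomacentrinae duplicates, and
three outgroup tips carrying A114/S118, uniform 0.1 branch lengths. On it,
parsimony and ML both label the root AS; ML additionally gives the
damselfish crown node AS, while parsimony prefers A118 there — exactly the
kind of model sensitivity the dual implementation is meant to expose.

## Expression

Proportions follow T_i/T_all = N_i/ΣN_i with N_i = mapped reads/CDS length,
computed within single-cone and double-cone classes separately. Groups with
zero total reads yield missing (NaN) proportions, not zeros. Rows with
non-positive CDS length and genes without a cone-class assignment are
rejected loudly. The "expressed" call for an SWS1 paralogue uses proportion
> 0.01 of single-cone expression — the original cutoff is unstated, so the
threshold is a config knob echoed into output metadata.

## Spectra

- **T50**: 0.5 × max(value), linearly interpolated at the
  longest-wavelength upward crossing — ocular media are long-pass, so the
  biologically meaningful cutoff is the final rise and early noise blips are
  ignored. Exactly 400 nm classifies as UV-blocking (strict inequality for
  transmitting). Flat or always-above-threshold spectra are degenerate and
  reported with a note at the first sample rather than rejected.
- **UV reflectance**: the published definition (reflection below 400 nm)
  sets no amplitude; this package calls a spectrum UV-reflective when its
  300–400 nm peak is ≥ 20% of the overall peak (configurable, echoed in
  output). Original reflectance calls therefore cannot be replicated
  exactly without the original spectra.
- **Templates**: Govardovskii A1 nomogram (α and β bands), normalized to
  peak 1; bandwidth grows with λ_max as the nomogram prescribes.
  Co-expression mixtures are weight-normalized sums renormalized to peak 1.
- Resampling is linear interpolation restricted to the shared wavelength
  range; no extrapolation.

## Synthetic data

One seed fans out to fixed per-generator substreams, so adding a generator
never changes existing outputs. Defaults are the stated study world: a
balanced 8-tip tree (branch length 0.1) with the short pigment planted in
one half and the long in the other over an AS root; background substitution
probability 0.005/site/branch avoiding the tuning sites (so planted states
stay exact — substitution-only evolution also keeps numbering an identity
map); one single-species gain plus one clade gain (the shape of the observed
duplication history); 10⁶ reads over realistic ~1 kb opsin CDS lengths with
single-cone truth (0.45, 0.25, 0.30); logistic lens curves with midpoint
380 nm, width 10 nm, noise 0.5%. What the generator does **not** emulate:
indels and rate heterogeneity in sequences, mapping bias and overdispersion
in counts, instrument baselines in spectra. A green recovery test therefore
establishes correctness of the estimators under their own model assumptions,
not robustness to real-data artefacts.

## Known limitations

- λ_max predictions inherit the panel's values; with the packaged default
  panel they are class-level (short/long/intermediate), not nm-accurate.
- The Mk model ignores among-site rate variation and uses a uniform root
  prior; joint (as opposed to marginal) ML reconstruction is not provided.
- Gain-event parsimony does not model duplication/loss rates; it reports
  minimum-event histories under the chosen costs only.
- Trees are consumed, never inferred.
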