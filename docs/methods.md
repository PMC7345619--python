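# Methods

## Identification model

The workflow treats compound identification as ranked retrieval against a
curated library. Its assumptions, in order of application:

1. **Adduct assumption.** Every precursor is [M+H]⁺ in positive mode or
   [M−H]⁻ in negative mode; the neutral mass is obtained by subtracting or
   adding one proton mass, taken as 1.007276 Da. No other adducts, in-source
   fragments, or isotopologue peaks are considered.
2. **Candidate retrieval.** The library stores neutral monoisotopic masses
   of MS-Ready structures (desalted, neutral forms). A candidate set is all
   records within ±10 ppm of the query's neutral mass. The ppm deviation is
   computed against the *candidate's* mass (the denominator convention is
   immaterial at 10 ppm but fixed for reproducibility); the window is
   symmetric in relative terms, so widening the tolerance can only add
   candidates. Candidates lacking predicted spectra stay in the set with a
   raw score of 0 and an explicit `no_predicted_data` flag — set
   composition matters for within-set normalisation even when a member
   cannot be spectrally scored.
3. **Spectral scoring.** Cosine dot product over one-to-one peak matches
   within 0.02 Da, norms over all peaks of both spectra, per collision
   energy (10/20/40 eV), summed into a raw score in [0, 3]. Energies absent
   on either side contribute zero; summation (rather than averaging over
   available energies) deliberately rewards coverage.
4. **Metadata fusion.** Within each candidate set, raw scores and
   data-source counts are divided by the set maximum; the combined score is
   the unweighted sum (weights are exposed but default 1:1). PubMed
   reference counts, PubChem source counts and NORMAN SusDat membership are
   carried through for reporting but excluded from the default combined
   score: fusing multiple priors does not outperform the data-source count
   alone, and a single prior keeps the ranking auditable.
5. **Confidence screening.** The quotient — raw score over the set-maximum
   raw score — flags identifications whose spectral evidence is weak
   *relative to their own candidate set*. The default cutoff 0.13
   corresponds to a 0.90 true-positive rate operating point; the screen is
   inclusive (quotient ≥ cutoff passes). The cutoff can be re-derived from
   labelled data as the largest threshold retaining the target fraction of
   true positives.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| precursor tolerance | 10 | ppm | symmetric, relative to candidate mass |
| peak match tolerance | 0.02 | Da | absolute, fragment-level |
| cosine exponents (a, b) | 0, 1 | – | plain cosine; (1, 0.5) gives Stein–Scott weighting |
| collision energies | 10/20/40 | eV | raw score ceiling = number of energies = 3 |
| combined weights | 1 : 1 | – | normalised MS/MS : normalised data-source count |
| quotient cutoff | 0.13 | – | inclusive; TPR-0.90 operating point |

## Numerical and procedural choices

* **Peak matching.** All in-tolerance pairs are accepted greedily in
  ascending |Δm/z| order (ties broken by peak indices), giving a
  deterministic one-to-one matching in O(P log P) for P candidate pairs.
  Whenever the pooled peaks of both spectra form tolerance-linked clusters
  of at most two members, the matching is forced and equals the
  minimum-total-|Δm/z| assignment; in denser clusters the greedy result is
  a maximal matching and therefore contains at least half as many pairs as
  any matching (the classic maximal-matching bound). Both regimes are
  exercised against a Hungarian-algorithm oracle in the test suite. The
  precursor peak is not removed before matching — no filtering is applied
  that the scoring definition does not call for.
* **Zero-intensity peaks** are retained by the parsers (losslessness) and
  excluded by the scorer before weighting; a spectrum with no positive
  intensity has an undefined cosine and raises rather than returning 0.
* **Exact self-similarity.** The cosine denominator is computed as
  `sqrt(‖w_q‖²·‖w_r‖²)` with the same summation path as the matched-pair
  dot product, so a spectrum scored against itself yields exactly 1.0 in
  floating point; scores are clamped to [0, 1] against rounding.
* **Tie handling in ranks.** Pessimistic competition ranking: every member
  of a tie group receives the group's worst rank. This never inflates top-k
  counts and makes ranks a pure function of the score values, hence
  invariant under candidate input order.
* **Normalisation** is division by the set maximum, not min–max scaling,
  so the normalised MS/MS score coincides with the quotient; min–max is
  available behind a switch. All-zero sets normalise to all zeros.
* **Cutoff selection.** With n true positives sorted by quotient, the
  TPR-targeted cutoff is the ⌈target·n⌉-th largest true-positive quotient —
  the largest threshold whose empirical TPR meets the target (verified
  against an exhaustive sweep). A target of 0 degenerates to the maximum
  observed quotient. Because the empirical TPR is a step function, the
  achieved training TPR generally overshoots the target; generalisation is
  judged by the holdout TPR's closeness to the *training* TPR.
* **Quartiles** use linear interpolation (NumPy default, type 7); box-plot
  edges derived from the reports depend on this convention.
* **Evaluation denominators.** Knowns absent from the library, or lacking
  predicted spectra under the spectral/combined schemes, are counted in a
  dedicated unranked column, never as a worst rank; percentages are
  reported both per all queries and per ranked knowns, which makes
  database-presence ("boosting") effects measurable.
* **Merged vs paired scoring.** Challenge-style inputs are one merged peak
  list per acquisition; the merged query is scored against each predicted
  energy and the scores summed (default). When per-energy query spectra
  exist, paired mode scores each against its matching predicted energy. In
  paired mode a noise-free query of a library compound scores exactly 3.0.
  In merged mode it cannot: the merged list is a superposition of three
  non-proportional energy spectra, and a cosine of 1.0 against *each* of
  them would require the three to be scalar multiples of one another,
  which would erase the energy dependence the library encodes. The
  merged-mode guarantee is relational instead — the true compound still
  maximises the raw score in its candidate set (quotient 1.0) — and that
  is the property the perfect-recovery tests assert.

## The synthetic benchmark

What it emulates, and the defaults defining the standard study conditions
(500 compounds in 100–800 Da, 100 queries, seed-determined):

* **Isobaric clusters** — 60% of compounds are placed in clusters of 2–12
  members within ±3 ppm of a shared base mass; cluster members share an
  InChIKey skeleton and differ in the second block, emulating stereoisomer
  multiplicity (the dominant source of multiple skeleton hits in real
  curated libraries). All other masses are kept ≥ 40 ppm apart so that,
  with the 1 ppm simulated precursor accuracy, non-cluster candidate sets
  are singletons by construction.
* **Toy fragmentation** — each compound gets 5–15 fragment positions at
  uniform fractions (0.08–0.92) of its precursor mass, shared across
  energies; the precursor's share of total ion current equals 0.85/0.45/
  0.08 at 10/20/40 eV, and an exponential tilt (0/1.2/2.5) shifts fragment
  weight toward low mass as energy rises. This reproduces the *shape* of
  collision-energy dependence that justifies summing per-energy scores,
  nothing more.
* **Metadata** — data-source counts are Zipf(1.6) (heavy-tailed, most
  compounds in one or two sources, a few ubiquitous), multiplied by
  `truth_ds_bias` for the true compounds: 5 in the standard conditions
  (knowns are well-catalogued chemicals), 0.2 in the "obscure" preset
  (knowns rarer than their decoys — the regime in which adding metadata to
  the ranking demonstrably stops helping and can hurt).
* **Acquisition noise** — per-peak dropout (p = 0.2), Gaussian m/z jitter
  (sd 0.005 Da, a quarter of the match tolerance), multiplicative
  lognormal intensity noise (CV 0.2), Poisson contaminants (2 expected
  extra peaks per query), 1 ppm precursor jitter. Noise vectors are drawn
  at full peak-list size before the dropout mask is applied, so runs that
  differ only in a noise level stay coupled under a fixed seed — raising
  dropout removes peaks from an otherwise identical realisation, which is
  what makes "more dropout never helps the truth" testable without
  Monte-Carlo averaging.

What it does **not** emulate: real fragmentation chemistry (no bond
energetics, no neutral losses shared between related structures), isotope
envelopes, chimeric spectra, retention time, and — importantly —
*correlated* spectra among structurally related compounds: decoy spectra
are independent of the truth's, so spectral confusability between cluster
members is much lower than for real stereoisomers and close analogues
(whose predicted spectra can be identical). Passing benchmarks therefore
validate the machinery — retrieval exactness, score arithmetic,
normalisation, ranking and screening logic, and the *direction* of
metadata effects — not the absolute identification rates one would obtain
on real contest data against a large predicted-spectrum database.

## Problem sizes

The test suite and the acceptance script run the standard conditions
(500 × 100) for the benchmark-level checks, 10⁴ records × 10³ queries for
the retrieval oracle, and 10³ random instances for the matching oracle;
the complete suite executes in well under a minute on one CPU, and the
acceptance script in a few seconds.

## Known limitations

* Only [M+H]⁺/[M−H]⁻; multiply charged species and other adducts are out
  of scope.
* The greedy matcher can (rarely, in dense clusters) select fewer or
  different pairs than the optimal assignment; the deviation is bounded and
  characterised but not eliminated.
* The quotient is a *relative* screen: it is blind to the absolute quality
  of the spectral match and therefore meaningless outside the context of
  the searched library; raw scores should always be carried alongside it.
* The curation audit relies on explicit isotope/charge flags on records; no
  structure perception is performed.
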