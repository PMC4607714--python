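# Methods

`sarqc` implements the automated portion of the activity/assay/target
curation workflow used by large literature-extracted bioactivity
databases, as a standalone, testable pipeline. This note records the
model behind each stage, the defaults and why, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## The curation model

A corpus is a table of per-measurement activity records. Each record
keeps the *published* type, relation, value and units verbatim — the
audit trail back to the source publication — and gains *standard*
counterparts plus at most one data-validity comment, a separate
potential-duplicate flag, and (when eligible) a pChEMBL value. The
pipeline only ever annotates: it never deletes, reorders or rewrites
published fields, so its output row count always equals its input and
re-running it on its own output is a no-op.

The seven steps, in order:

1. **Missing data.** A record with neither a published value nor an
   activity comment (e.g. "Not active") carries no information and is
   flagged `Potential missing data`.
2. **Non-standard units.** After standardization, a record whose units
   are not in the allowed set for its standard type (including absent
   units) is flagged `Non standard unit for type`. Types without a
   declared allowed set are exempt — the rule is opt-in per type.
3. **Log conversion.** Logarithmic types (pKi, pIC50, logIC50, ...) are
   unlogged to the nM scale. For negative-log types the censoring
   relation flips (pKi > 6 means Ki < 1000 nM). This step is part of
   standardization; the report row counts the records it touched.
4. **Typical ranges.** Values outside an inclusive per-(type, unit) range
   are flagged `Outside typical range`. The default dose-response range
   is 0.01 nM – 100 µM. Fragment compounds (MW < 350 Da) are genuinely
   weak binders, so their *upper* bound is multiplied by a relaxation
   factor (default 100); relaxation can only ever unflag.
5. **Duplicate citations.** Within groups sharing (compound, target,
   standard type, standard units) — the target resolved through the
   assay — cross-document pairs whose values are equal, or equal after
   rounding either member to 1–3 significant figures, are citation
   clusters. Every member outside the earliest document is marked
   `potential_duplicate`. Repeats within one document are never flagged
   (racemate + stereoisomer reporting is legitimate).
6. **Transcription errors.** Cross-document pairs whose mantissas match
   under the same rounding-aware rule but whose magnitudes differ by
   exactly 3 or 6 decades are unit slips (µM for nM, mM for nM). The
   records from the later documents are flagged
   `Potential transcription error`. Within a matched cluster, a later
   member whose value still matches an earliest-document value is a
   faithful citation, not a slip, and is left to step 5.
7. **pChEMBL.** For dose-response types (IC50, XC50, EC50, AC50, Ki, Kd,
   Potency) with units nM, relation `=`, a positive value and no
   validity comment: pChEMBL = 9 − log10(value/nM), rounded to two
   decimals. The duplicate flag is not a validity comment and does not
   suppress pChEMBL.

### Comment precedence

One comment per record. Steps run in order and never overwrite, with one
deliberate exception: step 6 may *upgrade* `Outside typical range` to
`Potential transcription error`. A 1000-fold unit slip of a typical value
usually lands outside the typical range, and the slip is the more
specific diagnosis — without the upgrade, most genuine transcription
errors would be reported merely as outliers. Missing-data and
non-standard-unit comments are never replaced.

## Standardization details

* **Type synonyms** are matched case-insensitively with whitespace and
  parentheses stripped ('Half life', 'half-life', 't(1/2)' → `T1/2`).
  Unknown types pass through with whitespace collapsed.
* **Unit dialects** are matched after normalizing case, the Greek mu, and
  the separators (space, `×`, `*`, `·` → `.`). Conversion never crosses
  dimension classes: molar dialects go to nM, mass-per-volume to
  µg·mL⁻¹, exposure (AUC) to ng·h·mL⁻¹, time to hr. Mass↔molar
  conversion via molecular weight is intentionally not performed.
  The shipped table is a representative, extensible subset (32 molar,
  15 mass, 12 exposure, 11 time dialects); production databases maintain
  far larger internal tables of the same shape.
* **Unlogging** is configurable per log type: whether the log is negative
  and whether its reference scale is M or nM (defaults: negative, M —
  `logIC50` is plain log of M). 10^(9−x) is computed in one step so
  integer pKi values unlog exactly.
* **Rounding** is two-tier and arithmetic (half-up, via `decimal` on the
  shortest round-tripping repr, so it acts on the printed value rather
  than binary noise): |v| < 10 → 3 significant figures (strict `<`, as
  the rule is stated); otherwise two decimal places. Banker's rounding
  was rejected as not "arithmetic". Rounding happens once, after
  conversion.
* **Failure is data, not an exception**: an unknown unit, a dialect from
  the wrong dimension class, or a non-positive concentration leaves the
  published value/units in the standard fields and the record is caught
  by step 2.

## Redundancy detection numerics

Values are compared after standardization (a µM-vs-nM citation pair
becomes a clean 10³ ratio) with relative tolerance 10⁻⁶; exact decade
ratios survive decimal→binary conversion well within this bound. The
significant-figure match is one-sided in either direction (round a to
1–3 sf and compare with b, or vice versa), not both-sided, which would
merge unrelated neighbours like 109 and 111. Document order is year
ascending with lexicographic document-id tie-break; records with unknown
year sort last, so an undated citation is flagged in preference to the
dated original. Output is invariant under permutation of the input and,
on every group, equal to an independently written O(n²) brute-force
oracle (tested on 1000 random groups).

## pChEMBL identity

For pKi values at printed precision (≤ 2 decimals) the pipeline's
pChEMBL reproduces the published pKi exactly: unlogging and 3-sig-fig /
2-decimal value rounding perturb the log by at most ~0.0022, and the
final 2-decimal pChEMBL rounding snaps back onto the grid point. For
arbitrary-precision inputs the two rounding stages can combine to ~0.007,
which is why the identity is stated — and probed — at printed precision,
with the acceptance tolerance ±0.005. The probe disables range flagging
(a pKi of 2 is a perfectly valid number whose unlogged value merely falls
outside the stringent default range, and any comment suppresses pChEMBL
by design).

## Assay and target annotation

Assay-type assignment and BAO-format classification are rule-based
surrogates for expert manual curation. Keyword tiers are configuration;
the precedence between tiers is the contract: ADME beats binding
(a cytochrome P450 assay is filed under A, not B); physicochemical
requires the absence of biological-target context; cytotoxicity resolves
to F in a therapeutic (efficacy-model) context and T otherwise, driven by
an explicit input flag — inferring disease context from text is out of
scope. Format precedence is organism > tissue > cell > biochemical,
because cues from more complex systems subsume simpler ones. The
cell-line dictionary maps tokens to candidate identities; more than one
candidate (the classic 'H4' rat-hepatoma/human-neuroglioma collision)
means organism context is required. Target records enforce the taxonomy
invariants: SINGLE PROTEIN has exactly one component; PROTEIN FAMILY,
PROTEIN COMPLEX and PROTEIN COMPLEX GROUP have at least two; a declared
binding subunit must be a component.

## The synthetic corpus

Each compound–target pair has a true potency drawn from
Normal(6.5, 1.5²) on the −log10 M scale; each independent measurement
adds Normal(0, 0.5²) of inter-assay noise — plausible medicinal-chemistry
scales. Measurements for a pair are spread over distinct documents
(years 1980+i). Later-document measurements become, with the configured
probabilities, citations of the pair's original (copied exactly or
rounded to 2–3 significant figures), or decade slips (the *printed*,
2–3-significant-figure mantissa times 10^±3 or 10^±6 — a later paper
reprints the tabulated value with the wrong units, not the full-precision
standardized one). Records are rendered in random molar dialects
(nM/µM/mM/M/pM spellings) or as log types with probability 0.2 (matching
the roughly one-fifth of records that arrive logarithmic); rendering is
exactly consistent, i.e. re-standardizing the published fields reproduces
the intended standard values bit-for-bit. Defaults
(300 compounds × 6 targets, 2–5 measurements/pair, p_citation = 0.05,
p_transcription = 0.02, p_missing = 0.01, 10 % fragments) give ~6,300
records — large enough for several hundred multi-document groups while
keeping the full suite under half a minute.

Ground truth labels every injection; out-of-range labels are assigned to
any rendered value outside the configured range (tail-of-distribution or
citation alike), excluding decade slips, which the pipeline deliberately
reports under the more specific comment. `evaluate_flags` scores each
flag class as precision/recall against these labels, undefined when a
denominator is zero.

Because citations always copy the pair's earliest document and dialects
stay molar, recall of injected citations and slips is structurally 1.0
for any seed; precision may dip below 1.0 through honest coincidences
(two independent measurements agreeing at 1 significant figure across
documents). None of this shows the detectors would achieve such recall on
real corpora, where citations cross type/unit groups, originals predate
database coverage, and values collide for physical reasons.

## Known limitations

* Keyword-based assay annotation is a triage aid, not curation; it has no
  notion of negation or context windows.
* The conversion table is deliberately finite; unlisted dialects are
  flagged rather than guessed.
* Duplicate detection cannot distinguish a citation from a genuinely
  re-measured identical value; that ambiguity is inherent to the rule.
* Cross-database reconciliation, compound-structure standardization,
  ontology resolution (EFO/CLO/Uberon/BAO URIs) and statistical outlier
  detection are out of scope.
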