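# Methods

This note documents the models, estimators and design choices behind
analogkit, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic-data tests do and do not demonstrate.

## Generic dictionary and enumeration

The design space is a *generic dictionary* of small modifications, each a
fragment SMILES with exactly one attachment dummy `[*]`:

* functional groups (the shipped spec lists 30 from a standard
  medicinal-chemistry repertoire: alkyls, halogens, CF3/OCF3, cyano, nitro,
  alcohols/ethers, amines/amides, acids/esters, sulfonyl groups, alkenes
  and alkynes);
* monocyclic ring cores of sizes 3–6 — carbocyclic plus one- and
  two-heteroatom N/O rings (22 cores) — either bare or decorated with one
  of three groups (methyl, fluoro, methoxy) at a relative ring position;
* C/O/N spacers of length 0–2 inserted between the attachment dummy and
  the payload (13 compositions).

Decoration positions are relative to the attachment atom measured as
ring-walk distance: ortho = 1, meta = 2, para = 3. Ortho/meta/para are all
meaningful only on 6-membered rings; 4- and 5-membered rings expose
none/ortho/meta (one adjacent, one non-adjacent position) and 3-membered
rings none/ortho. The attachment atom of a ring core is the first ring
atom bearing a hydrogen; when the walked-to decoration atom has no free
valence the other ring direction is tried, and the combination is skipped
if neither works. The full cross product is sanitized, deduplicated by
canonical fragment SMILES and ordered lexicographically, so rebuilding from
the same spec reproduces the identical entry set (the spec's SHA-256 digest
is stored alongside). The shipped spec yields 2368 unique fragments.

Attachment replaces the dummy with a single bond to a user-chosen seed atom,
either consuming one hydrogen (`substitute_hydrogen`) or first deleting the
lowest-index terminal heavy neighbor (`replace_terminal_group`). Ring
fusions and spiro attachments are deliberately out of scope. Libraries are
exhaustive over (site × entry): every close analog is kept — there is no
diversity pruning, because the campaign style this supports wants dense
local SAR around the seed. Products are deduplicated by canonical isomeric
SMILES, the single identity notion used everywhere (enumeration, filtering,
ledger keys, tests).

## Standardization and filtering

Standardization = RDKit cleanup → neutralization of safe charges →
canonical tautomer (RDKit's deterministic tautomer canonicalizer). It is
idempotent; permanent charges (quaternary N) pass through with a logged
note. Full microspecies distributions and pKa models are out of scope: the
single neutral species is a pH-7.4 approximation.

Physchem profiles are computed on the canonical re-parsed graph, making
them bit-stable and independent of input atom ordering. logP is the
Wildman–Crippen (1999) atomic-contribution scheme as implemented in the
pinned RDKit version. Default property windows — MW ≤ 650, logP ≤ 6,
rotatable bonds ≤ 12 — are campaign-tunable defaults chosen to pass
seed-sized chemistry while cutting pathological enumeration products; they
are not literature constants. The alert list is a small curated
reactive/promiscuous-substructure set in the PAINS spirit (nitro, azide,
peroxide, acyl/sulfonyl halides, Michael acceptors, …); production
campaigns should swap in a full published list via config. The filter
report satisfies the accounting identity (retained + first-rule rejections
= input) and window tightening is monotone by construction.

## Template-constrained 3D evaluation

The reference pose is the seed's bioactive conformation (from SDF, a PDB
ligand record, or a seeded ETKDG embedding in tests). For each analog:

1. **Mapping** — maximum common connected substructure under element and
   exact bond-order compatibility (RDKit FMCS), tie-broken to the
   lexicographically smallest mapped index sequence; mappings below 5 atoms
   (configurable) are rejected.
2. **Embedding** — ETKDGv3 with a fixed random seed (bit-reproducible),
   followed by MMFF94 (UFF fallback) cleanup.
3. **Superposition** — closed-form least-squares rigid fit (Kabsch/SVD with
   reflection exclusion) over the mapped atoms; the minimized mapped-atom
   RMSD is reported and the whole molecule is transformed.
4. **Clashes** — a heavy-atom pair clashes when d < scale × (r_i + r_j)
   with Bondi vdW radii and default scale 0.7; intra-ligand pairs separated
   by ≤ 3 bonds (1-2/1-3/1-4) are excluded. Counts are monotone in scale.
5. **Torsion strain** — a minimal shipped rule set (sp3–sp3 chains,
   aryl–carbonyl, amide omega, biaryl) keyed by 4-atom path SMARTS with
   allowed |dihedral| windows; matched torsions outside every window count
   as strained, unmatched torsions are unscored. This is intentionally a
   small, inspectable rule file, not a full published torsion library.
6. **Priority** — score = −w·clashes − w·strain − w·RMSD + w·physchem
   compliance, with non-negative weights (defaults 1.0/1.0/0.5 strain/0.25
   RMSD/1.0 physchem) and ties broken by canonical text. The score is a
   deliberately transparent surrogate for proprietary template-docking
   scorers: it reproduces the shape of the decision procedure (penalize
   clashes, strain and template deviation; reward drug-likeness) without
   estimating binding affinity. Lowering any penalty term can never lower
   a compound's rank.

No flexible docking, pose sampling, binding free-energy estimation or
crystallographic handling is attempted.

## Assay estimators

**Melting temperature.** Tm is the midpoint of a Boltzmann sigmoid
F(T) = bottom + (top−bottom)/(1+exp((Tm−T)/slope)) fitted by least squares;
if the fit fails or is implausible, the argmax of the smoothed dF/dT is
used. Flat curves raise a no-transition error. ΔTm = Tm(holo) − Tm(apo) is
signed (destabilization allowed) and antisymmetric.

**Enzymatic velocity.** The NADH-decay trace is scanned over all contiguous
windows of ≥ 30 % of the points; among windows whose linear fit reaches
R² ≥ 0.99 (configurable), the highest-R² window wins (R² rounded to 1e-6 so
near-ties resolve toward longer windows, then earlier starts). Flat
windows are defined as perfectly linear with slope 0, so a globally flat
trace yields velocity 0 flagged degenerate rather than an error. Activity
is the velocity magnitude normalized to the drug-free control: ratios > 1
mean activation, < 1 inhibition — the representation in which an
activator-to-inhibitor switch of a compound series is read directly.

**Dose–response.** 4PL model R(c) = bottom + (top−bottom)/(1+(c/IC50)^h),
free Hill slope, top/bottom bounded to [0, 120] % unless overridden. The
*technical floor* models the resolution limit of enzymatic IC50s: an IC50
cannot be resolved below the enzyme concentration (100 nM, or 50 nM in
low-enzyme runs), so a fitted value below the floor is reported censored
as "< floor" and never enters ledger ratios.

**ITC.** The independent-sites isotherm: the cell species carries one or
two site classes (n_j, K_D,j, ΔH_j); free titrant is solved from the mass
balance by bracketed root finding and the model heat per mole of injectant
is the increment of total bound heat between injections. The cell
concentration is treated as constant across the titration (injection
volumes are not part of the isotherm record; the small-volume approximation
is shared by the synthetic generator, so recovery tests are exact in the
model). Reverse titrations — protein in the syringe, compound in the cell,
used in practice to dodge compound solubility limits — are handled by role
exchange, under which the binding polynomial is symmetric. The two-site
fit is seeded from the one-site optimum plus a weak 100×-looser second
site, which guarantees the nested-model residual ordering; when the two
fitted log K_D confidence intervals (±2 SE from the Gauss–Newton
covariance) overlap, the result is flagged parameter-indistinguishable —
the expected outcome of fitting two sites to monophasic data.

## SAR ledger

Long-format CSV (id, parent, field, value, comparator, units, provenance).
The shipped table contains only the published milestone values of the dCK
campaign — masitinib (ΔTm 7.4 °C, K_D 1400 nM), dCKi1 (14.3 °C, 128 nM,
cellular IC50 6900 nM), dCKi2 (17.3 °C, 37 nM, 8900 nM), OR0274 → OR0642
(cellular IC50 2096 → 2.2 nM) and the negative control OR0659 (enzymatic
IC50 censored > 100 µM) — each row carrying a provenance string; the
roughly 60 other synthesized compounds of the campaign are user-loadable,
not shipped. OR0634 merges the modifications of OR0602 and OR0624; the
single parent field records OR0602 (which keeps cellular potency strictly
improving along the main path), with the hybrid origin noted in the
provenance. OR0602's ΔTm was only reported qualitatively and is left
blank. Censored values never enter fold-changes; fold_change(a,b) ×
fold_change(b,a) = 1 for uncensored values; parent edges must form a
forest (cycles and self-parents are integrity errors).

## Synthetic data: what it does and does not show

Generators are deterministic given (parameters, seed) down to the byte,
and every written fixture carries a manifest with its ground truth. Noise
is additive Gaussian on fluorescence/heat; dose grids are log-spaced over
the cellular assay's working range (10 pM – 40 µM, 8 concentrations,
triplicates); ITC defaults use the reverse-titration geometry (80 µM cell,
400 µM syringe, 15 injections to molar ratio 2.5); pocket fixtures are
pseudo-carbon shells placed 4 Å beyond the ligand's extent (≥ 12 Å radius),
clash-free by construction.

Passing recovery tests therefore shows that the estimators invert their own
generating models at realistic noise — Tm to ±0.2 °C at 2 % amplitude
noise, 4PL IC50 unbiased within 10 % over 200 Monte-Carlo draws at 3 %
noise, one-site K_D to 5 % noiseless and two-site constants to 20 % under
seeded noise. It does not certify behavior on real instrument artifacts:
post-transition fluorescence decay in melt curves, injection baseline
drift and dilution heats in ITC, or cooperative binding, none of which the
generators emulate.

## Numerical and interface choices

* Units: °C, seconds, nM (molar internally in the ITC solver), kcal/mol,
  Å; coordinates in a right-handed frame; 0-based atom indexing in all
  APIs and files.
* All randomness flows from explicit integer seeds; enumeration and
  filtering are deterministic without any seed.
* Degenerate inputs fail loudly with typed exceptions (no transition, no
  linear range, no binding signal, degenerate alignment, empty library,
  empty selection) rather than returning NaNs.
* The pipeline report echoes its effective config and a SHA-256 digest of
  the timing-independent content, so reruns are verifiable.
* Known limitations: no reaction-based or stereoisomer enumeration; no
  pKa/ADMET models; no displacement/competition ITC models; torsion rules
  are a minimal curated set; the priority score is ordinal, not an
  affinity estimate.
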