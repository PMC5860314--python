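# Methods

## The decomposition model

A *rigid fragment* is a connected heavy-atom substructure in which rotation
about any internal bond moves hydrogens only. Rigidity — not synthetic
accessibility — is the cut criterion, because a rigid body can be docked in
one pass with no conformational search; this is what makes fragment-level
docking orders of magnitude cheaper than compound-level docking, and it cuts
far more bonds than retrosynthetic schemes (RECAP/BRICS-style rules leave
large flexible fragments and defeat deduplication).

Bond classification marks as rigid: all ring bonds (ring systems are treated
as rigid bodies, saturated rings included — ring puckering is ignored at
pre-screening accuracy), all double/triple/aromatic bonds, acyclic single
bonds between two sp/sp² atoms (conjugation/resonance locking), and amide
C–N bonds. Two deliberate exceptions restore strict heavy-atom rigidity
where the hybridization wording would over-merge:

* **Biaryl-type linkages.** An acyclic single bond joining two ring atoms is
  cleavable even when both atoms are sp². A biphenyl-like bond twists freely
  (real biaryl torsion profiles are soft); merging the two rings would
  create a fragment whose heavy atoms move under that torsion. Rigidity
  takes precedence.
* **Exotic/hypervalent centres.** Atoms outside {B, C, N, O, F, P, S, Cl,
  Br, I} or exceeding their charge-adjusted default valence (e.g. sulfone
  sulfur) have all their acyclic single bonds cleaved. Conservative: no
  rigidity claim is made for chemistry the rules were not designed around.

Groups are the connected components over rigid bonds; single-atom leftovers
are *solitary*. A solitary atom with one or two adjacent groups, at least
one non-solitary, is merged into **each** adjacent non-solitary group — a
CH₂ bridging two rings is duplicated into both ring fragments, so each
fragment keeps the local geometry of its attachment. A solitary atom with
three or more adjacent groups stays a single-atom fragment (merging it into
one neighbor would orphan the others' geometry and merging into all would
duplicate it more than the attachment context justifies); solitary–solitary
pairs never merge, and merging is single-pass, since transitive growth would
chain sp³ atoms into flexible fragments. Users needing a strict atom
partition can set `merge_mode="unique"`, which assigns a bridging atom to
the larger adjacent group (tie → lower canonical atom rank); the default
duplicating behavior is recorded in the library metadata.

Every valence vacated by a cut bond is filled with one hydrogen; degenerate
single-atom fragments cap to the hydride (CH₄, NH₃, H₂O, …). Stereo
descriptors on atoms incident to cut bonds are erased (the stereo context no
longer exists); stereo interior to a fragment is kept. The
*cleaved-bond count* of a compound is the number of parent bonds contained
in no fragment; under the duplicating merge a bridge bond "saved" inside one
duplicate copy is not counted as cleaved, and for strict partitions the
count equals (fragments − 1) on acyclic group trees.

## Fragment keys and deduplication

The deduplication key is RDKit canonical isomeric SMILES of the capped
fragment, with RDKit's default aromaticity model. Two fragments with
isomorphic capped structures (hydrogen counts included) key identically
regardless of input atom order; the key doubles as a stable join column for
external score tables. Multiplicity is stored per compound: a fragment
occurring twice contributes two copies of its score to SUM/GS (the sums run
over a compound's fragments, not over unique keys); MAX is unaffected.

## Scoring semantics

Backends are score-only: the protocol deliberately discards poses, since
pre-screened candidates are re-docked properly afterwards. Each fragment is
scored at its own best location, independently of its siblings — fragment
collisions are accepted as the price of speed. Where several rows per key
are ingested (poses, repeated runs) the minimum (most favorable) raw score
is kept. Raw scores are ΔG-like; inversion s → max(0, −s) is applied before
*all* formulas, giving every aggregate a uniform higher-is-better
orientation and making unfavorable (positive) fragments exactly neutral.
Missing fragment scores contribute zero by default with a warning; a strict
mode raises instead. The GS exponent is any real x ≥ 1; GS is evaluated as
m·(Σ(sᵢ/m)ˣ)^{1/x} with m the maximum, so x = 200 does not overflow.
Ranking is descending with lexicographic ID tie-break; reruns are
byte-identical.

The mock backend used by tests and benchmarks is a pure function of the
canonical key and a seed: −(0.3·heavy + 0.1·hetero + u) with u a
SHA-256-derived uniform deviate in [0, noise_scale = 1). The 0.3 kcal/mol
per heavy atom slope is a typical ligand-efficiency magnitude and
reproduces docking's size bias (bigger fragments score better), which is
the bias the volume cutoff exists to counter. It models no shape or
electrostatic complementarity whatsoever: benchmark results validate the
bookkeeping and aggregation, never docking physics.

## Volume cutoff

Compound volume V_c is estimated by atomic contributions:
V = Σ atoms − 5.92·N_bonds − 14.7·R_aromatic − 3.8·R_nonaromatic (Å³),
hydrogen atoms and their bonds counted, rings from the SSSR, with the
published element contribution table (C 20.58, H 7.24, N 15.60, O 14.71, …).
A compound is omitted when V_c strictly exceeds k·V_p; the boundary is kept.
V_p is an input (pocket-detection tools provide it); k absorbs cavity
flexibility, and the 1.5 default errs toward keeping borderline compounds —
in a pre-screen a false negative is unrecoverable while a false positive
merely wastes one docking run.

## Evaluation

EF_x% uses top-window size max(1, ⌊x·N⌋). EF is undefined (an error) when
the ranked set contains no actives. In the two-stage screen the EF
denominator is always the full library, so actives discarded by the
pre-screen count against the method. Note the attainable maximum is
min(1/x, All₁₀₀/Pos₁₀₀) — the window size caps EF even for a perfect
ranking. Structural-diversity helpers use 2048-bit radius-2 Morgan
fingerprints (ECFP4-equivalent) and max-Tanimoto against an active set.

## Synthetic data

The generator emulates one property of real libraries: derivative richness.
Hard-coded vocabularies of 36 saturated ring cores and 35 aromatic ring
substituents — all pairwise non-isomorphic after capping — are joined by one
cleavable single bond, so an n×m grid decomposes to exactly n+m unique
fragments: an exact oracle for deduplication. Randomized stress libraries
interpose acyclic linkers (chains, conjugated bridges, amides, branching
carbons) to exercise every bond-classification rule. Benchmarks define
activity through composition: actives draw their substituent from a
privileged subset (3 substituents by default) whose mock scores are shifted
by −δ; decoys sample the rest with replacement. Defaults: 25 actives, 2475
decoys (a 1% active rate, matching the EF1% window), δ = 4.0 — about four
noise standard deviations, a clearly separable but not degenerate signal.
What passing these benchmarks shows: decomposition, deduplication,
score-sharing, inversion, aggregation, ranking and EF arithmetic are
correct. What it cannot show: screening power on real targets, where scores
come from physics and actives are not composed from privileged parts.

## Numerical and design notes

* Problem sizes in tests and the acceptance script (1000-molecule rigidity
  sweeps, 2500-compound benchmarks, 2000-permutation EF calibrations,
  200-replicate fit studies) were chosen to give stable statistics on a
  single CPU in seconds; all are pure functions of their seeds.
* GS₂₀₀ ≈ MAX convergence is checked on multisets of pairwise-distinct
  values drawn from a coarse grid: with k-fold ties at the maximum
  GS_x − MAX = m·(k^{1/x} − 1) decays only like log k/x, so the 10⁻²
  agreement bound is mathematically meaningful only for separated values
  (adjacent grid ratio ≤ 0.95 ⇒ gap < 10⁻⁵ at x = 200).
* The two-factor OLS fit (SUM score, cleaved-bond count → reference
  compound score) refuses rank-deficient designs and names the degenerate
  feature; the training correlation is reported as NaN for constant
  targets/predictions (detected by zero range, not zero variance, to avoid
  float-summation artifacts).
* Salts/multi-component inputs keep the largest covalent component (logged).
  logP values always travel with the method name (Crippen–Wildman), since
  logP estimates are method-dependent.
* Null-calibration of the benchmark (δ = 0) averages EF1% over 500 reseeds
  of the privileged/active draw and the score noise on a fixed 500-compound
  grid; the mean is ≈ 1 and the check bounds it in [0.7, 1.3] (active
  selection correlates with shared substituents, inflating the variance but
  not the mean).

## Known limitations

* Rigidity is binary: slightly hindered rotors (ortho-substituted biaryls,
  conjugated esters) are treated as fully cleavable, and macrocycle or
  ring-conformer flexibility is not modeled.
* Fragment scores ignore inter-fragment collisions and linker strain, so
  SUM-type aggregates overestimate large, fragment-rich compounds — the
  documented size bias that the volume cutoff only partially offsets.
* Tautomers and protonation states are taken as given; no enumeration.
* The volume estimate is a bond-count-corrected atomic sum — fast, but blind
  to conformation; V_p quality is entirely the user's responsibility.
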