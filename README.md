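# fragscreen

Ultrafast docking-based **pre-screening** of compound libraries by
rigid-fragment decomposition.

Structure-based virtual screening ranks candidate molecules by docking them
into a protein pocket, but full flexible docking of tens of millions of
compounds is computationally out of reach. `fragscreen` implements a
pre-screening protocol that makes docking-based triage cheap enough for
database-scale libraries:

1. **Decompose** every compound into *rigid fragments* — connected
   substructures with no heavy-atom torsional degree of freedom. Rings stay
   whole (even cyclohexane), double/triple/aromatic bonds, conjugated
   sp²–sp² linkages and amide C–N bonds are never cut; everything else is,
   with each broken valence capped by a hydrogen.
2. **Deduplicate** fragments across the whole library by canonical key.
   Derivative-rich libraries share fragments heavily, so the number of
   unique fragments is far smaller than the number of compounds — each
   fragment is docked (scored) only once and its score is reused by every
   compound containing it.
3. **Score** each unique fragment with any docking backend that emits a
   scalar (a deterministic mock backend is built in for tests and
   benchmarks; fragments can be exported to SDF and external scores
   ingested from TSV).
4. **Aggregate and rank.** Raw ΔG-like scores are inverted,
   s<sub>f</sub> = max(0, −score<sub>f</sub>), and each compound is scored
   by one of

   - SUM  = Σ<sub>f</sub> s<sub>f</sub>
   - MAX  = max<sub>f</sub> s<sub>f</sub>
   - GS<sub>x</sub> = (Σ<sub>f</sub> s<sub>f</sub><sup>x</sup>)<sup>1/x</sup>

   GS<sub>1</sub> = SUM, GS<sub>∞</sub> = MAX; the default GS<sub>3</sub>
   weights a compound's few best fragments without discarding the rest.
5. **Filter and evaluate.** Compounds too big for the pocket are omitted
   when their atomic-contribution volume estimate V<sub>c</sub> exceeds
   k·V<sub>p</sub> (cavity volume V<sub>p</sub> supplied by the user,
   flexibility multiplier k = 1.5 by default). Ranked screens are evaluated
   with enrichment factors

   EF<sub>x%</sub> = (Pos<sub>x%</sub>/All<sub>x%</sub>) / (Pos<sub>100%</sub>/All<sub>100%</sub>),

   including the two-stage protocol (pre-screen top *a*%, re-rank the
   survivors with an expensive reference score, report EF<sub>b%</sub>
   against the full library).

The package is aimed at computational chemists who need a fast, transparent
triage step in front of an expensive docking campaign, and at method
developers who want a reference implementation of fragment-score
aggregation with exact, testable semantics.

## Worked example

A planted-signal benchmark: 500 compounds built from ring cores ×
substituents, 10 actives whose substituents carry a −4 kcal/mol score
offset, deterministic mock docking scores.

```python
import fragscreen as fs
from fragscreen.fixtures import FixtureSpec, gen_benchmark

bench = gen_benchmark(FixtureSpec(n_actives=10, n_decoys=490, delta=4.0, seed=7))
lib = bench.library
print(f"{lib.n_compounds} compounds -> {lib.n_unique_fragments} unique fragments "
      f"(reduction {fs.reduction_ratio(lib):.1f}x)")

scores = fs.score_all(lib, bench.score_table, fs.FormulaSpec("gs", 3))
ranking = fs.rank_compounds(scores)
for cid, score, rank in ranking[:3]:
    print(f"  rank {rank}: {cid}  GS3 = {score:.3f}")

ranked_ids = [cid for cid, _, _ in ranking]
print(f"EF1% = {fs.enrichment_factor(ranked_ids, bench.actives, 0.01):.1f}")
```

Output:

```
500 compounds -> 20 unique fragments (reduction 25.0x)
  rank 1: A00006  GS3 = 6.727
  rank 2: A00000  GS3 = 6.725
  rank 3: A00004  GS3 = 6.690
EF1% = 50.0
```

The 500 compounds deduplicate to 20 unique fragments, so a docking backend
would run 25× fewer simulations than compound-level docking. All five
top-1% slots are occupied by actives (IDs `A…`), giving the maximal
EF<sub>1%</sub> for 10 actives in 500 compounds: (5/5)/(10/500) = 50.

The same workflow is available from the shell:

```bash
fragscreen gen-fixtures benchmark --actives 10 --decoys 490 --delta 4 --seed 7 --out-dir bench/
fragscreen rank --lib bench/ --scores bench/scores.tsv --formula gs --x 3 --out ranking.tsv
fragscreen screen --config run.cfg --out-dir out/   # full pipeline incl. cutoff + EF
```

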