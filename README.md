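# mogsa — Modified Green Star Area greenness scoring

`mogsa` scores the "greenness" of a chemical reaction or process against a
user-selected subset of the 12 Green Chemistry principles (Anastas &
Warner), from GHS hazard statements and declared reaction metadata. It is
aimed at bench chemists, process developers and instructors who want a
quick, auditable sustainability comparison between synthetic routes
without a full life-cycle assessment.

## The metric

Every substance in the reaction carries its GHS H-codes. Each code maps
to a severity score S ∈ {1, 2, 3} (Low / Moderate / High) within its
hazard class — physical (H2xx), health (H3xx), environmental (H4xx) —
via a fixed published table shipped with the package; degradability and
renewability are scored on the same scale. Each applicable principle Pᵢ
then earns points

```
pᵢ = 4 − S      (S = worst-case severity over the substances in the principle's scope)
```

or is scored directly from declared metadata (excess reagents and
byproducts for P2, temperature/pressure for P6, renewable feedstock
count for P7, derivatization count for P8, monitoring mode for P11).
The overall score over the n ≥ 1 applicable principles is the normalized
points sum

```
MoGSA = 100 · Σ pᵢ / (3 n)        ∈ [33.33, 100]
```

banded as **unacceptable** (< 50), **acceptable** (50–75) or
**excellent** (≥ 75). Principles marked non-applicable enter neither
numerator nor denominator and render as yellow sectors in the star;
scored sectors are green (3), half green / half red (2) or red (1).

## Worked example

Score the packaged whole-cell biocatalysis example:

```python
from importlib import resources
from mogsa import load_assessment, assess_all, compute_score

path = resources.files("mogsa") / "data/fixtures/acetophenone_fungal.reconstruction.yaml"
a = load_assessment(path)
result = compute_score(assess_all(a), title=a.title)
print(result.summary())
```

prints

```
Biocatalysis 2 (Galactomyces candidus whole cells): MoGSA score 80.00 (excellent)
  applicable principles: 10/12
   P1 Prevention                                    3/3
   P2 Atom Economy                                  3/3
   P3 Less Hazardous Chemical Synthesis             2/3
   P4 Designing Safer Chemicals                     N/A
   P5 Safer Solvents and Auxiliary Substances       2/3
   P6 Increase Energy Efficiency                    3/3
   P7 Use Renewable Feedstocks                      2/3
   P8 Reduce Derivatives                            2/3
   P9 Catalysts                                     3/3
  P10 Design for Degradation                        2/3
  P11 Real-Time Analysis for Pollution Prevention   N/A
  P12 Safer Chemistry for Accident Prevention       2/3
```

Ten principles are applicable (the target molecule's design, P4, and
real-time monitoring, P11, are excluded from this comparison); they earn
24 of 30 possible points, so the score is 100 × 24/30 = 80.00, in the
excellent band. The same pipeline from the shell, plus a rendered star:

```
mogsa demo --out examples          # write the packaged example files
mogsa assess examples/acetophenone_fungal.reconstruction.yaml --out results
mogsa compare examples/acetophenone_*.yaml --out results
```

`assess` writes a JSON report and a deterministic SVG star per input;
`compare` writes a ranked CSV/text table and a band-colored bar chart.
`mogsa validate` schema-checks input files, and `--exclude P4,P11`
masks principles from the command line.

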