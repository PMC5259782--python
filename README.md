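# cladekin

Tools for asking, end to end, the question "which single residue makes one
taxonomic group's enzyme behave differently?" — built around the analysis
that identified the residue governing allosteric inhibition of
cyanobacterial phosphoenolpyruvate carboxylase (PEPC, the enzyme that
carboxylates phosphoenolpyruvate with bicarbonate to oxaloacetate).

It is a library for three kinds of users: the sequence analyst who has a
protein family alignment and order/clade labels and wants candidate
specificity-determining positions; the phylogeneticist who wants a quick
distance tree with bootstrap support to confirm that the clades are real;
and the enzymologist with coupled-assay data who needs Michaelis–Menten
parameters, effector relative activities and inhibition-mode calls.

## What it computes

**Residue scan.** Over an alignment with clade labels, two filters:
*reference-unique* columns, where the reference sequence carries a residue
no other sequence has; and *clade-discriminating* columns, where a target
clade's consensus residue has frequency ≥ θ (default 0.9) and differs from
every contrast clade's consensus. Their intersection, reported at the
reference's ungapped positions (1-based from the initiator methionine), is
the candidate list — the screen that singles out a position like E954.
Gapped↔ungapped coordinate maps transfer positions between homologs (e.g.
position 954 in one enzyme ↔ 946 in another). The Ikai aliphatic index
Ai = 100·(X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu)) is included for
thermostability comparisons.

**Phylogeny.** p-distances or Poisson-corrected distances (−ln(1−p)) over
chosen columns, Saitou–Nei neighbor joining (exact on additive matrices),
column-resampling bootstrap with a mandatory seed, monophyly tests, and
Newick I/O via dendropy. NJ is a deliberate desk-scale stand-in for
maximum-likelihood inference; it answers the order-level clustering
questions posed here.

**Kinetics.** Initial rates from A340 traces of the NADH-coupled assay
(velocity = |dA/dt| / 6.22 per cm·mL, in units = µmol NADH·min⁻¹);
Michaelis–Menten fits by the classical Lineweaver–Burk double-reciprocal
regression (1/v on 1/[S]; intercepts 1/Vmax and −1/Km) with nonlinear
least squares as the statistically preferred cross-check; specific
activity (units/mg, units/pmol, implied subunit mass); effector relative
activity (% of mock ± SD, paired two-tailed t-test); inhibition-mode
classification from relative Vmax/Km changes; pH/temperature optimum
detection on measured grids.

**Synthetic data.** Generators with recorded ground truth for all of the
above: clade-structured alignments with planted signal columns and indels,
Michaelis–Menten assay tables with multiplicative replicate noise and
multiplicative effector factors, absorbance traces, and Gaussian activity
profiles. Every generator is a pure function of (config, seed).

## Worked example

```sh
python examples/kinetics_fit.py
```

prints

```
  MOCK: Km = 0.340 mM, Vmax = 1.740 units/mg (r^2 = 1.000000, LB)
malate: Km = 0.816 mM, Vmax = 2.192 units/mg (r^2 = 1.000000, LB)
malate mode: Km-and-Vmax-increase (malate/fumarate-type)
NLS cross-check: Km = 0.340 mM (agrees with LB on clean data)
```

A noiseless PEP titration generated at Vmax = 1.74 units/mg (4 pmol =
0.6 µg of enzyme) and Km = 0.34 mM comes back from the double-reciprocal
fit with exactly those numbers — the fitting stage is distortion-free —
and an effector that multiplies Vmax by 1.26 and Km by 2.4 is classified
as the mixed "Km-and-Vmax-increase" signature rather than textbook
competitive inhibition. The other scripts in `examples/` walk through the
residue scan, the bootstrap tree, the effector panel with t-tests, and
optimum detection the same way.

A thin CLI wraps the same functions for file-based runs:

```sh
cladekin simulate --kind msa --seed 6 --out msa.fasta
cladekin scan --msa msa.fasta --clades msa.clades.tsv --ref CladeA_1 \
    --target-clade CladeB --contrast-clades CladeA,CladeC --out sites.tsv
cladekin tree --msa msa.fasta --reps 500 --seed 6 --out tree.nwk
```

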