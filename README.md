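# rnaneutralset

Fast, sample-free estimation of RNA secondary-structure **neutral set sizes**
from free-energy arguments.

## The problem

The neutral set of an RNA secondary structure is the set of sequences that
fold into it; its size strongly influences which structures can arise and
persist in evolution.  Computing it directly means folding astronomically many
sequences, and established sample-based estimators still need thousands of
structure predictions per structure.  This package implements an analytic
alternative that needs a *single* free-energy bookkeeping pass per structure,
plus everything required to validate it: exact structure-space counting and
uniform sampling, competing sample-free baselines, and a sample-based
nested-set reference estimator.

Two set-size notions are supported for a structure *A* of length *L*:

* the **low-energy set size** N_A(G ≤ x): sequences that fold into *A* with
  free energy at most x (not necessarily as their preferred structure);
* the **mfe set size** N_mfe: sequences whose minimum-free-energy structure is
  *A*, approximated here by N(G ≤ x_heuristic) with the per-structure cut-off
  x_heuristic = (1.5 − n_bp) kcal/mol.

## The method

Only compatible sequences — one of the six legal pairs (AU, UA, GC, CG, GU,
UG) at every paired position — can fold into *A* at all; there are exactly

    N_c = 4^(L − 2 n_bp) · 6^n_bp

of them.  The estimator asks which fraction of these meets the energy
criterion.  The sequence-independent loop free energy G_loop (Turner
nearest-neighbour loop initiation terms) must be offset by sequence-dependent
stabilisation from stacking terms (n_stack of them) and merged dangling-end /
terminal-mismatch "end-of-stack" terms (n_eos, each worth at least
a = 0.5 kcal/mol), so each stacking term must supply

    G_stacking = [x − (G_loop − a·n_eos)] / n_stack.

The required G_stacking is translated into per-site *versatilities* — v = 1
for unconstrained sites down to v_bp = 2/6 for GC/CG-only pairs and
v_eos = 1/4 for fully constrained end-of-stack sites — by linear interpolation
between the endpoints (−0.5, 1) and (−3.0, 2/6) for pairs, with a cascade of
end-of-stack fallbacks when stacking alone is insufficient.  The estimate is

    N(G ≤ x) ≈ N_c · v_eos^n_eos · v_bp^n_bp ,

multiplied by 0.1 if even fully constrained sequences cannot reach x.
See `docs/methods.md` for the full cascade, assumptions and limitations.

## Worked example

```python
>>> from rnaneutralset import estimate_mfe_set_size, parse_structure
>>> s = parse_structure("((((((...........))))))" + "." * 12)  # L = 35, one helix of 6 bp
>>> est = estimate_mfe_set_size(s)
>>> est.x, est.branch.value
(-4.5, 'interpolated')
>>> round(est.v_bp, 3), est.v_eos
(0.595, 1.0)
>>> round(est.log10_size, 2)
17.16
```

The heuristic cut-off for 6 base pairs is x = 1.5 − 6 = −4.5 kcal/mol.  The
11-base hairpin costs G_loop = 6.6 kcal/mol, so each of the five stacking
terms must supply about −2.0 kcal/mol: paired sites are partially constrained
(v_bp ≈ 0.60, between GC-only 1/3 and unconstrained 1) while the two
end-of-stack sites stay free, giving an estimated mfe set of 10^17.2 sequences
out of N_c = 4^23·6^6 ≈ 10^18.5 compatible ones.

From the shell:

```bash
$ rnaneutralset count -L 35
13399136
$ echo "((..((...))..))...................." | rnaneutralset estimate /dev/stdin --heuristic
```

The first command counts all valid structures of length 35 (minimum hairpin
3, no lonely pairs) — about 1.3 × 10⁷.  Other subcommands: `features`,
`enumerate`, `sample` (uniform, seeded, optional designability filter),
`baselines`, `reference` (sample-based nested-set estimates) and `compare`
(Pearson-on-logs, log–log r², RMSD of log10 values).

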