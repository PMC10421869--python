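# clockrank

Network-topology prioritization of core-clock-associated candidate proteins
in protein–protein interaction (PPI) networks.

Given an undirected PPI network and a small seed set of core circadian
clock proteins, `clockrank` proposes and filters candidate clock-associated
proteins using two complementary local-topology miners, each validated by a
permutation test and an annotation-coherence filter:

1. **RWR branch** — random walk with restart
   `P_{i+1} = (1−r)·W·P_i + r·P_0` (column-stochastic `W`, restart `r=0.8`,
   L1 stopping tolerance `1e-6`); nodes with stationary probability
   `> 1e-5` are raw candidates. Significance: empirical FDR
   `p(g) = θ/n` against `n` random seed sets of the same size
   (`θ` = strict exceedances), keeping `p < 0.05`.
2. **GDV branch** — per-node graphlet degree vectors over the 15
   automorphism orbits of the 2–4-node graphlets (11 non-redundant orbits
   by default), on the degree-≥3-filtered network; signature similarity
   `S_GDV(u,v) = 1 − Σ|u_i−v_i| / Σ(u_i+v_i)` with an adaptive threshold
   (start 0.96, step down 0.01 until every seed has a non-seed match).
   Significance: `p(g) = θ/n` against degree-preserving rewired networks
   (attempted double edge swaps), keeping `p < 0.05`.

Surviving candidates from either branch must then reach a **maximum
annotation similarity (MAS) ≥ 0.75 in both** a GO-type and a pathway-type
namespace, where MAS is the candidate's best cosine similarity `Γ` between
hypergeometric enrichment vectors `ES(g)` (per-term
`S(g,A) = −log10 P(X ≥ m)` over the closed neighborhood) against any seed.
The final output is the union of the two branches with provenance flags.

See `docs/methods.md` for the full model description and design notes.

## Worked example

Everything runs end to end on a generated benchmark — a scale-free network
with a planted, densely wired, annotation-enriched 30-node module whose
members are the known ground truth:

```python
import clockrank as cr
from clockrank.permutation import NullEnsembleConfig
from clockrank.pipeline import PipelineConfig

inst = cr.generate(cr.GeneratorConfig(rng_seed=1))   # 800 nodes, 9 seeds
cfg = PipelineConfig(null=NullEnsembleConfig(n_permutations=200), rng_seed=1)
out = cr.run_pipeline(inst.network, inst.seeds,
                      inst.annotations_go, inst.annotations_pathway, cfg)
print({k: out.report[k] for k in
       ("raw_rwr", "candidate_rwr", "final_rwr",
        "gdv_threshold", "raw_gdv", "candidate_gdv", "final_gdv",
        "final_union", "overlap")})
print(cr.evaluate_recovery(inst, set(out.table["node"])))
```

prints

```
{'raw_rwr': 324, 'candidate_rwr': 33, 'final_rwr': 18,
 'gdv_threshold': 0.89, 'raw_gdv': 23, 'candidate_gdv': 6, 'final_gdv': 6,
 'final_union': 20, 'overlap': 4}
(0.95, 0.9047619047619048)
```

Reading: of 800 nodes, 324 exceed the walk-probability threshold; the
random-seed-set permutation trims them to 33 and the dual-namespace MAS
filter to 18. The GDV threshold search settles at 0.89; 23 wiring-similar
raw candidates shrink to 6 significant ones, all 6 passing MAS. The union
is 20 unique candidates (4 found by both branches), of which 19 are true
planted-module members — precision 0.95, recall 19/21 ≈ 0.90.

The same pipeline is scriptable from the shell:

```bash
clockrank simulate --out-dir bench/ --seed 1
clockrank run --config run.yaml --out-dir results/   # paths + parameters in YAML
# or stage by stage:
clockrank rwr  --network bench/net.tsv --seeds bench/seeds.txt --out rwr_raw.tsv
clockrank gdv  --network bench/net.tsv --seeds bench/seeds.txt --out gdv_raw.tsv
```

Inputs are plain text: two-column TSV or SIF edge lists, one-id-per-line
seed files, GMT or two-column TSV annotation maps.

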