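# phylodca

Phylogeny-aware correction of Potts-model (DCA) inference from
multiple-sequence alignments.

Standard direct coupling analysis treats the rows of an MSA as independent
samples, which biases the estimated frequencies whenever the sequences share
ancestry. This package corrects for that bias when the phylogeny is known:

1. **Rate fit** — estimate the effective per-site mutation rate from the
   Hamming-distance vs. patristic-time curve of all leaf pairs
   (`phylodca.rate_fit`).
2. **Site correction** — maximize, per MSA column, the Felsenstein-pruning
   likelihood of an independent-site evolution model over its stationary
   profile ω_i (`phylodca.site_pruning`).
3. **Pair correction** — likewise per column pair over the joint table
   ω_ij, parameterized by a coupling matrix with compensatory fields so the
   single-site marginals stay pinned to the site-corrected profiles
   (`phylodca.pair_pruning`).
4. **MSA rebuild** — draw a profile MSA from the corrected profiles and
   anneal within-column swaps (Metropolis on the Frobenius distance between
   connected-correlation tensors) toward the corrected pair statistics
   (`phylodca.msa_builder`).
5. **Inference** — run pseudo-likelihood maximization on the rebuilt MSA
   (`phylodca.plm_dca`).

A built-in simulator (`phylodca.phylo_sim`) generates ground-truth data: a
sparse toy Potts model (L=25, q=4, mean degree 3), a binary clock tree of
2^K leaves, and biased (tree) / fair (i.i.d.) Gibbs samples. The evaluation
harness (`phylodca.evaluation`) scores every inference arm against the known
model: Pearson/slope of frequency recovery, symmetrized Kullback–Leibler
divergence by MCMC, contact PPV from zero-sum-gauge coupling norms, and
single-mutant energy-shift correlations.

## Command-line interface

All commands live under a single entry point:

```bash
phylodca simulate --K 10 --mu-l-dt 3 --out-prefix runs/toy
phylodca estimate-mu  --msa runs/toy.tree.fasta --tree runs/toy.nwk
phylodca correct-site --msa runs/toy.tree.fasta --tree runs/toy.nwk \
    --mu auto --out runs/omega_site.tsv
phylodca correct-pair --msa runs/toy.tree.fasta --tree runs/toy.nwk \
    --omega-site runs/omega_site.tsv --mu auto --out runs/omega_pair.tsv
phylodca build-msa --profile runs/omega_site.tsv --pairs runs/omega_pair.tsv \
    --out runs/corrected.fasta
phylodca infer-plm --msa runs/corrected.fasta --out runs/model.txt
phylodca evaluate --truth runs/toy.model.txt --inferred runs/model.txt \
    --contacts runs/toy.contacts.tsv --out runs/eval.json
phylodca run-experiment --preset mu-l-dt-3 --reps 2 --K 6 --out runs/report
```

Inputs are aligned FASTA and Newick with branch lengths (trees are consumed,
never inferred — use external software such as FastTree for real protein
families and feed the result in). Tabular outputs are TSV, summaries JSON;
every command writes a `<out>.config.json` log with the resolved settings
and seed. A TOML file can supply `run-experiment` settings via `--config`
(command-line flags win).

## Layout

| module | contents |
| --- | --- |
| `potts_core` | Potts model type, toy-model generator, energies, zero-sum gauge, coupling scores, mutant tables, plain-text model format |
| `phylo_sim` | tree/MSA types, binary-tree growth, branch evolution, tree & i.i.d. Gibbs sampling, Newick conversion |
| `freq_stats` | frequencies, connected correlations, Hamming, 80%-identity reweighting, Pearson/slope comparison |
| `rate_fit` | leaf-pair patristic times, distance-curve binning, exponential rate fit |
| `site_pruning` | single-site propagator, pruning likelihood, stochastic profile optimizer |
| `pair_pruning` | pair propagator, pair pruning likelihood, compensatory-field scaling, constrained optimizer |
| `msa_builder` | corrected-statistics combination, profile MSA sampling, simulated-annealing swap sampler |
| `plm_dca` | pseudo-likelihood maximization, profile-model baseline |
| `evaluation` | symmetrized KL, PPV curves, mutant-effect scores, repetition harness |
| `io_cli` | FASTA/Newick/TSV/model I/O and the `phylodca` CLI |
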