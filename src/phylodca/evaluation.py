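"""Evaluation of inferred models against the known ground truth.

Symmetrized KL divergence by MCMC, contact PPV from coupling scores,
mutational-effect correlation, and the multi-repetition experiment harness
that runs the uncorrected / reweighted / site-corrected / pair-corrected /
i.i.d. inference arms on simulated data.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import freq_stats, msa_builder, pair_pruning, phylo_sim, plm_dca, rate_fit, site_pruning
from .freq_stats import StationaryStats
from .phylo_sim import Msa
from .potts_core import (PottsModel, ToyModelParams, coupling_scores,
                         generate_toy_model, hamiltonian_batch,
                         mutational_effects, zero_sum_gauge)

__all__ = ["symmetrized_kl", "ppv_curve", "mutant_prediction_score",
           "ExperimentConfig", "run_experiment"]


def _subseed(*keys) -> int:
    s = int(np.random.SeedSequence(entropy=tuple(int(k) for k in keys)).generate_state(1)[0])
    return s % (2**31 - 1) or 1


def symmetrized_kl(p: PottsModel, q_model: PottsModel, n_samples: int = 10000,
                   burn_in: int | None = None, thinning: int | None = None,
                   seed=0, n_batches: int = 20):
    """MC estimate of D_KL(p||q) + D_KL(q||p) with a batch-means s.e.

    Equals <H_q - H_p>_p + <H_p - H_q>_q, estimated on Gibbs samples of each
    model (default thinning: L sweeps per recorded sequence).
    """
    if (p.L, p.q) != (q_model.L, q_model.q):
        raise ValueError("models must share L and q")
    if thinning is None:
        thinning = p.L
    terms = []
    variances = []
    for k, (ma, mb) in enumerate(((p, q_model), (q_model, p))):
        sample = phylo_sim.sample_iid(ma, n_samples, burn_in=burn_in,
                                      thinning=thinning,
                                      seed=_subseed(seed, k)).data
        diff = hamiltonian_batch(mb, sample) - hamiltonian_batch(ma, sample)
        terms.append(diff.mean())
        batches = np.array_split(diff, n_batches)
        means = np.array([b.mean() for b in batches])
        variances.append(means.var(ddof=1) / len(means))
    return float(terms[0] + terms[1]), float(np.sqrt(sum(variances)))


def ppv_curve(scores: np.ndarray, true_edges) -> np.ndarray:
    """Positive predictive value over the first N ranked pairs, N = 1..P.

    Pairs i < j are ranked by descending score with deterministic (i, j)
    lexicographic tie-breaking; PPV(N) is the fraction of true edges among
    the top N.
    """
    scores = np.asarray(scores, dtype=float)
    L = scores.shape[0]
    if scores.shape != (L, L):
        raise ValueError("scores must be a square matrix")
    edges = {(min(i, j), max(i, j)) for i, j in true_edges}
    iu, ju = np.triu_indices(L, k=1)
    vals = scores[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    hits = np.array([(int(iu[k]), int(ju[k])) in edges for k in order])
    return np.cumsum(hits) / np.arange(1, len(hits) + 1)


def mutant_prediction_score(true_model: PottsModel, inferred_model: PottsModel,
                            wt_set, train_msa: Msa | None = None) -> dict:
    """Mean Pearson between true and predicted single-mutant energy shifts.

    One correlation per wild type over its L(q-1) mutants, averaged over the
    set; zero-variance prediction vectors are skipped with a warning.  When a
    training MSA is supplied, the Hamming distance of each wild type to its
    nearest training sequence is reported for distance-resolved averages.
    """
    if (true_model.L, true_model.q) != (inferred_model.L, inferred_model.q):
        raise ValueError("models must share L and q")
    wt_data = wt_set.data if isinstance(wt_set, Msa) else np.asarray(wt_set)
    per_wt = []
    dists = []
    skipped = 0
    for wt in wt_data:
        t = mutational_effects(true_model, wt).delta_H
        p = mutational_effects(inferred_model, wt).delta_H
        if t.std() == 0 or p.std() == 0:
            skipped += 1
            per_wt.append(np.nan)
        else:
            per_wt.append(float(np.corrcoef(t, p)[0, 1]))
        if train_msa is not None:
            d = (train_msa.data.astype(np.int64) != np.asarray(wt, dtype=np.int64)[None, :]).sum(axis=1)
            dists.append(int(d.min()))
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate wild types", stacklevel=2)
    per_wt = np.array(per_wt, dtype=float)
    return {
        "mean_pearson": float(np.nanmean(per_wt)),
        "per_wt": per_wt,
        "nearest_train_distance": np.array(dists) if train_msa is not None else None,
    }


# ---------------------------------------------------------------------------
# repetition harness

KNOWN_ARMS = ("tree", "reweight", "site", "pair", "iid",
              "profile-tree", "profile-site")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of the tree-sampling / correction experiment."""

    toy: ToyModelParams = field(default_factory=ToyModelParams)
    K: int = 12
    mu_l_dt: float = 3.0  # expected mutation events per branch / L... times L
    dt: float = 0.3
    reps: int = 30
    seed: int = 0
    arms: tuple[str, ...] = ("tree", "site", "pair", "iid")
    site_schedule: site_pruning.OptimizerSchedule = field(
        default_factory=site_pruning.OptimizerSchedule)
    pair_schedule: site_pruning.OptimizerSchedule = field(
        default_factory=site_pruning.OptimizerSchedule)
    anneal: msa_builder.AnnealSchedule = field(
        default_factory=msa_builder.AnnealSchedule)
    lam_J: float = 0.01
    lam_h: float = 0.01
    n_wt: int = 50
    kl_samples: int = 10000
    mu_bins: int = 20
    max_pairs: int = rate_fit.DEFAULT_MAX_PAIRS

    def __post_init__(self) -> None:
        unknown = set(self.arms) - set(KNOWN_ARMS)
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")


def _needs(config, *arms) -> bool:
    return any(a in config.arms for a in arms)


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Run the repetition harness; returns a report dict, optionally as TSV.

    Per repetition: simulate a biased (tree) and a fair (i.i.d.) sample of
    the same ground-truth model, fit the effective mutation rate, run the
    requested correction/inference arms, and evaluate statistics accuracy,
    parameter recovery, symmetrized KL, contact PPV and mutant-effect scores.
    Identical configs (including seeds) produce identical reports.
    """
    model0, edges = generate_toy_model(config.toy)
    truth_scores = zero_sum_gauge(model0)
    L, q = model0.L, model0.q
    M = 2 ** config.K
    mu_sim = config.mu_l_dt / (L * config.dt)
    rows = []
    ppv_curves: dict[str, list[np.ndarray]] = {}
    for rep in range(config.reps):
        row: dict[str, float] = {"rep": rep}
        tree = phylo_sim.grow_binary_tree(config.K, config.dt)
        tree_msa = phylo_sim.sample_tree_msa(
            model0, tree, mu_sim, seed=_subseed(config.seed, rep, 1))
        iid_msa = phylo_sim.sample_iid(
            model0, M, seed=_subseed(config.seed, rep, 2))
        f_tree = freq_stats.count_frequencies(tree_msa)
        f_iid = freq_stats.count_frequencies(iid_msa)
        fit = rate_fit.estimate_mu(tree_msa, tree, n_bins=config.mu_bins,
                                   max_pairs=config.max_pairs,
                                   seed=_subseed(config.seed, rep, 3))
        row["mu_hat"] = fit.mu
        row["plateau_hat"] = fit.plateau
        row.update(_prefixed("f_site_tree", freq_stats.compare_stats(
            freq_stats.flatten_site(f_iid), freq_stats.flatten_site(f_tree))))

        omega_site = None
        if _needs(config, "site", "pair", "profile-site"):
            sched = dataclasses.replace(config.site_schedule,
                                        seed=_subseed(config.seed, rep, 4))
            omega_site = site_pruning.correct_all_sites(tree_msa, tree, fit.mu, sched)
            row.update(_prefixed("f_site_corrected", freq_stats.compare_stats(
                freq_stats.flatten_site(f_iid),
                freq_stats.flatten_site(omega_site))))

        omega_pair = None
        if _needs(config, "pair"):
            sched = dataclasses.replace(config.pair_schedule,
                                        seed=_subseed(config.seed, rep, 5))
            omega_pair = pair_pruning.correct_all_pairs(
                tree_msa, tree, fit.mu, omega_site, sched)
            row.update(_prefixed("f_pair_tree", freq_stats.compare_stats(
                freq_stats.flatten_pair(f_iid), freq_stats.flatten_pair(f_tree))))
            row.update(_prefixed("f_pair_corrected", freq_stats.compare_stats(
                freq_stats.flatten_pair(f_iid),
                freq_stats.flatten_pair(omega_pair))))
            row.update(_prefixed("c_pair_tree", freq_stats.compare_stats(
                freq_stats.connected_correlations(f_iid).ravel(),
                freq_stats.connected_correlations(f_tree).ravel())))
            row.update(_prefixed("c_pair_corrected", freq_stats.compare_stats(
                freq_stats.connected_correlations(f_iid).ravel(),
                freq_stats.connected_correlations(omega_pair).ravel())))

        models: dict[str, PottsModel] = {}
        for arm in config.arms:
            per_arm_failures = []
            try:
                models[arm] = _run_arm(arm, config, rep, model0, tree_msa,
                                       iid_msa, f_tree, omega_site, omega_pair,
                                       row)
            except Exception as exc:  # noqa: BLE001 - isolate arm failures
                per_arm_failures.append((arm, repr(exc)))
                warnings.warn(f"arm {arm!r} failed in rep {rep}: {exc!r}",
                              stacklevel=2)

        rng = np.random.default_rng(_subseed(config.seed, rep, 6))
        wt_tree = tree_msa.data[rng.choice(tree_msa.M,
                                           size=min(config.n_wt, tree_msa.M),
                                           replace=False)]
        wt_fair = iid_msa.data[rng.choice(iid_msa.M,
                                          size=min(config.n_wt, iid_msa.M),
                                          replace=False)]
        for arm, model in models.items():
            zs = zero_sum_gauge(model)
            row[f"pearson_J_{arm}"] = _safe_pearson(truth_scores.J.ravel(), zs.J.ravel())
            row[f"pearson_h_{arm}"] = _safe_pearson(truth_scores.h.ravel(), zs.h.ravel())
            kl, kl_se = symmetrized_kl(model0, model,
                                       n_samples=config.kl_samples,
                                       seed=_subseed(config.seed, rep, 7))
            row[f"kl_{arm}"] = kl
            row[f"kl_se_{arm}"] = kl_se
            curve = ppv_curve(coupling_scores(model), edges)
            ppv_curves.setdefault(arm, []).append(curve)
            row[f"ppv_at_E_{arm}"] = float(curve[len(edges) - 1]) if edges else np.nan
            row[f"mut_tree_{arm}"] = mutant_prediction_score(
                model0, model, wt_tree)["mean_pearson"]
            row[f"mut_fair_{arm}"] = mutant_prediction_score(
                model0, model, wt_fair)["mean_pearson"]
        rows.append(row)

    keys = sorted({k for row in rows for k in row})
    summary = {}
    for k in keys:
        vals = np.array([row[k] for row in rows if k in row], dtype=float)
        if len(vals):
            summary[f"mean_{k}"] = float(np.nanmean(vals))
    report = {
        "per_rep": rows,
        "summary": summary,
        "n_edges": len(edges),
        "edges": sorted(edges),
        "ppv_curves": {arm: np.mean(np.array(c), axis=0).tolist()
                       for arm, c in ppv_curves.items()},
    }
    if outdir is not None:
        _write_report(report, config, outdir)
    return report


def _run_arm(arm, config, rep, model0, tree_msa, iid_msa, f_tree, omega_site,
             omega_pair, row) -> PottsModel:
    lam = {"lam_J": config.lam_J, "lam_h": config.lam_h}
    if arm == "tree":
        return plm_dca.plm_infer(tree_msa, **lam)
    if arm == "reweight":
        w = freq_stats.reweighting_weights(tree_msa)
        return plm_dca.plm_infer(tree_msa, weights=w, **lam)
    if arm == "iid":
        return plm_dca.plm_infer(iid_msa, **lam)
    if arm == "profile-tree":
        return plm_dca.fit_profile(f_tree)
    if arm == "profile-site":
        return plm_dca.fit_profile(omega_site)
    if arm in ("site", "pair"):
        if arm == "site":
            target = msa_builder.combine_site_correction(f_tree, omega_site)
            row["combined_out_of_range"] = target.out_of_range
        else:
            target = omega_pair
        profile = StationaryStats(site=target.site,
                                  provenance=target.provenance,
                                  out_of_range=target.out_of_range)
        arm_id = KNOWN_ARMS.index(arm)
        art = msa_builder.init_profile_msa(profile, tree_msa.M,
                                           seed=_subseed(config.seed, rep, 8,
                                                         arm_id),
                                           alphabet=tree_msa.alphabet)
        sched = dataclasses.replace(config.anneal,
                                    seed=_subseed(config.seed, rep, 9, arm_id))
        art, _, _ = msa_builder.anneal_msa(art, target, sched)
        return plm_dca.plm_infer(art, **lam)
    raise ValueError(f"unknown arm {arm!r}")


def _prefixed(prefix: str, d: dict) -> dict:
    return {f"{k}_{prefix}": v for k, v in d.items()}


def _safe_pearson(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _write_report(report, config, outdir) -> None:
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report["per_rep"]).to_csv(out / "per_rep.tsv", sep="\t",
                                           index=False)
    pd.DataFrame({arm: curve for arm, curve in report["ppv_curves"].items()}
                 ).to_csv(out / "ppv_curves.tsv", sep="\t", index_label="N")
    with open(out / "summary.json", "w") as fh:
        json.dump({"summary": report["summary"],
                   "n_edges": report["n_edges"],
                   "config": _config_dict(config)}, fh, indent=2, default=str)


def _config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    return d
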