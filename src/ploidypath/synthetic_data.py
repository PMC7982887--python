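"""Synthetic island-lineage datasets with the statistical structure the
analysis assumes.

The generator emulates the study conditions at the level the models see:
a dated ultrametric (pure-birth) tree whose pendant branches play the role
of stem ages, archipelago membership drawn with the observed 98/23/23/6
proportions, exogenous predictors with Table-2-like marginals, and the two
endogenous responses generated from the causal diagram with phylogenetically
correlated (Brownian) noise whose per-lineage scale follows the observation
weights. Every run records the full ground truth, so the pipeline's
estimates can be scored for bias, RMSE, CI coverage and d-separation
calibration.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace as dc_replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .lineage_data import AnalysisDataset, LineageRecord, filter_lineages
from .path_sem import PathConfig, island_dag, run_path_analysis
from . import phylo_cov

logger = logging.getLogger("ploidypath")

#: Archipelago membership probabilities (observed lineage proportions).
DEFAULT_ARCH_PROBS = {"NZ": 98 / 150, "CI": 23 / 150, "HI": 23 / 150,
                      "JF": 6 / 150}

#: True coefficients of the endemic-diversity equation (ln endemic count),
#: in the design parameterization (treatment contrasts vs. NZ). The
#: PloidyChange -> EndemicDiversity entry is 0: that edge is absent from the
#: diagram, and a zero coefficient makes the generator diagram-consistent.
DEFAULT_ENDEMIC_COEFS = {
    "intercept": 0.2,
    "arch_CI": 0.0, "arch_HI": 0.5, "arch_JF": -0.6,
    "log_stem_age": 0.35,
    "ploidy_levels": 0.28,
    "ploidy_levels:arch_CI": 0.0, "ploidy_levels:arch_HI": 0.0,
    "ploidy_levels:arch_JF": 0.0,
    "source_pool": 0.0002,
    "monophyletic": 0.2,
    "ploidy_change": 0.0,
}

#: True coefficients of the ploidy-levels equation.
DEFAULT_PLOIDY_COEFS = {
    "intercept": 0.8,
    "arch_CI": 0.0, "arch_HI": 0.0, "arch_JF": 0.0,
    "log_stem_age": 0.15,
    "log_stem_age:arch_CI": 0.0, "log_stem_age:arch_HI": -0.35,
    "log_stem_age:arch_JF": 0.0,
    "source_pool": 0.002,
    "ploidy_change": 1.9,
}


@dataclass
class SimulationParams:
    """Conditions of one simulated study.

    Defaults emulate the compiled four-archipelago dataset: 150 lineages in
    the observed island proportions, stem ages with mean ~13 Myr, a
    log-normal source pool with median 51, Bernoulli rates 18/150 for a
    ploidy change and 67/150 for island monophyly, and Beta-distributed
    chromosome-count completeness with mean ~0.78.

    ``round_counts=True`` discretizes the responses (integer ploidy-level
    and endemic-species counts); ``False`` keeps the latent continuous
    responses, under which the fitted model is exactly correctly specified —
    the mode used for calibration and coverage studies.
    """

    n_lineages: int = 150
    arch_probs: dict = field(default_factory=lambda: dict(DEFAULT_ARCH_PROBS))
    birth_rate: float = 1.0
    mean_stem_age: float = 13.16        # Myr; tree is rescaled to match
    endemic_coefs: dict = field(
        default_factory=lambda: dict(DEFAULT_ENDEMIC_COEFS))
    ploidy_coefs: dict = field(
        default_factory=lambda: dict(DEFAULT_PLOIDY_COEFS))
    sigma_diversity: float = 0.8        # Brownian noise scale, ln endemic
    sigma_ploidy: float = 0.8           # Brownian noise scale, ploidy levels
    pool_log_mean: float = math.log(51.0)
    pool_log_sd: float = 1.5
    pool_max: float = 2000.0
    p_ploidy_change: float = 18 / 150
    p_monophyletic: float = 67 / 150
    age_sd_rel: float = 0.2             # stem-age SD ~ rel * age * lognormal
    age_sd_scatter: float = 0.5
    completeness_beta: tuple[float, float] = (0.94, 0.26)
    completeness_min: float = 0.3
    round_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_lineages < 2:
            raise ValueError("need at least 2 lineages")
        total = sum(self.arch_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("archipelago probabilities must sum to 1")
        for name in ("birth_rate", "sigma_diversity", "sigma_ploidy",
                     "mean_stem_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Trees and Brownian traits
# ---------------------------------------------------------------------------

def simulate_tree(n: int, birth_rate: float = 1.0,
                  seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n`` tips labeled L001...

    Reproducible: the same seed yields a bit-identical Newick string.
    """
    if n < 2:
        raise ValueError("need n >= 2 tips")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(birth_rate=birth_rate, death_rate=0.0,
                                    num_extant_tips=n, rng=rng)
    # The simulator stops at the nth speciation event, so the youngest tip
    # has a zero pendant branch; observe the process part-way to the next
    # event instead, keeping the tree ultrametric with positive stem edges.
    extra = rng.expovariate(n * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    width = max(3, len(str(n)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"L{i:0{width}d}"
    return tree


def simulate_brownian(tree: dendropy.Tree, sigma2: float,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Brownian trait vector over the tree's tips (tip-iteration order).

    Zero-mean, covariance ``sigma2 * C(tree)``, generated by accumulating
    independent normal increments along each branch from the root.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            incr = rng.normal(0.0, math.sqrt(sigma2 * node.edge.length))
            values[id(node)] = values[id(node.parent_node)] + incr
    for leaf in tree.leaf_node_iter():
        out.append(values[id(leaf)])
    return np.asarray(out)


def _unit_brownian(tree: dendropy.Tree,
                   rng: np.random.Generator) -> np.ndarray:
    """Brownian tip values standardized to unit variance per tip."""
    b = simulate_brownian(tree, 1.0, rng)
    depths = np.asarray(tree.calc_node_root_distances(
        return_leaf_distances_only=True))
    return b / np.sqrt(depths)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _linear_predictor(coefs: dict, arch: list[str], columns: dict,
                      varying_base: str) -> np.ndarray:
    """Evaluate a truth-coefficient dict in the design parameterization."""
    n = len(arch)
    eta = np.full(n, coefs.get("intercept", 0.0))
    ind = {a: np.asarray([1.0 if x == a else 0.0 for x in arch])
           for a in ("CI", "HI", "JF")}
    for a, dummy in ind.items():
        eta += coefs.get(f"arch_{a}", 0.0) * dummy
    for name, col in columns.items():
        eta += coefs.get(name, 0.0) * col
        if name == varying_base:
            for a, dummy in ind.items():
                eta += coefs.get(f"{name}:arch_{a}", 0.0) * col * dummy
    return eta


def simulate_dataset(params: SimulationParams,
                     ) -> tuple[AnalysisDataset, dendropy.Tree, dict]:
    """Draw one dataset from the causal diagram.

    Stem ages are the pendant branch lengths of a rescaled pure-birth tree;
    the two responses follow their linear predictors plus Brownian noise
    scaled per lineage by the observation-weight model the estimator
    assumes (variance multiplier 1/w). Returns the filtered analysis
    dataset (generated records always pass the inclusion criteria
    unchanged), the tree, and a ground-truth record.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_lineages

    tree = simulate_tree(n, params.birth_rate,
                         seed=int(rng.integers(2**31 - 1)))
    pendants = np.asarray([leaf.edge.length
                           for leaf in tree.leaf_node_iter()])
    scale = params.mean_stem_age / float(pendants.mean())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    stem_age = pendants * scale
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    arch_names = list(params.arch_probs)
    arch = [str(a) for a in rng.choice(
        arch_names, size=n, p=[params.arch_probs[a] for a in arch_names])]
    log_age = np.log(stem_age)
    pool = np.minimum(
        np.maximum(np.round(rng.lognormal(params.pool_log_mean,
                                          params.pool_log_sd, n)), 1.0),
        params.pool_max)
    chg = (rng.random(n) < params.p_ploidy_change).astype(float)
    mono = (rng.random(n) < params.p_monophyletic).astype(float)

    age_sd = params.age_sd_rel * stem_age * rng.lognormal(
        -params.age_sd_scatter**2 / 2, params.age_sd_scatter, n)
    w_species = 1.0 / np.sqrt(age_sd)

    a, b = params.completeness_beta
    completeness = np.maximum(rng.beta(a, b, n), params.completeness_min)
    completeness = np.minimum(completeness, 1.0)

    z_ploidy = _unit_brownian(tree, rng)
    z_div = _unit_brownian(tree, rng)

    # With discretized counts the completeness weight must survive the
    # pipeline's floor prop >= 1/n_endemic, while n_endemic itself depends
    # on ploidy; a short fixed-point loop resolves the circularity (the
    # floor moves completeness for at most a handful of small lineages).
    # With continuous latent responses no floor applies and one pass is
    # exact, leaving the fitted model correctly specified.
    for _ in range(6 if params.round_counts else 1):
        # "monophyletic" has no default entry: a nonzero truth coefficient
        # deliberately creates the RepeatColonization -> PloidyLevels path
        # the diagram omits, for misspecification studies.
        eta_p = _linear_predictor(
            params.ploidy_coefs, arch,
            {"log_stem_age": log_age, "source_pool": pool,
             "ploidy_change": chg, "monophyletic": mono},
            varying_base="log_stem_age")
        ploidy_latent = eta_p + params.sigma_ploidy * z_ploidy \
            / np.sqrt(completeness)
        if params.round_counts:
            ploidy = np.maximum(np.round(ploidy_latent), 1.0)
        else:
            ploidy = ploidy_latent

        eta_d = _linear_predictor(
            params.endemic_coefs, arch,
            {"log_stem_age": log_age, "ploidy_levels": ploidy,
             "source_pool": pool, "monophyletic": mono,
             "ploidy_change": chg},
            varying_base="ploidy_levels")
        log_endemic = eta_d + params.sigma_diversity * z_div \
            / np.sqrt(w_species)
        if params.round_counts:
            n_endemic = np.maximum(np.round(np.exp(log_endemic)), 1.0)
            floor = 1.0 / n_endemic
            needed = np.maximum(completeness, floor)
            if np.allclose(needed, completeness):
                completeness = needed
                break
            completeness = needed
        else:
            n_endemic = np.exp(log_endemic)

    n_native = np.maximum(np.ceil(n_endemic), 2.0) \
        + rng.binomial(3, 0.5, n)

    records = []
    for i in range(n):
        records.append(LineageRecord(
            lineage_id=labels[i], genus=f"Genus_{labels[i]}",
            archipelago=arch[i],
            n_native=float(n_native[i]), n_endemic=float(n_endemic[i]),
            n_ploidy_levels=float(ploidy[i]),
            monophyletic_on_island=bool(mono[i]),
            ploidy_change_vs_sister=bool(chg[i]),
            stem_age=float(stem_age[i]), stem_age_sd=float(age_sd[i]),
            source_pool_size=float(pool[i]),
            prop_chrom_counted=float(completeness[i]),
            has_dated_phylogeny=True, has_chromosome_count=True))
        if params.round_counts:
            # Continuous latent responses deliberately relax the
            # integer-count invariants, so only discretized datasets are
            # validated record by record.
            records[-1].validate()
    dataset = filter_lineages(records)
    assert len(dataset) == n, "generated records must pass filtering"

    truth = {
        "seed": params.seed,
        "round_counts": params.round_counts,
        "endemic": dict(params.endemic_coefs),
        "ploidy": dict(params.ploidy_coefs),
        "sigma_diversity": params.sigma_diversity,
        "sigma_ploidy": params.sigma_ploidy,
    }
    return dataset, tree, truth


# ---------------------------------------------------------------------------
# Recovery and calibration studies
# ---------------------------------------------------------------------------

#: Truth keys absent from a dataset's design (archipelagos not drawn) are
#: skipped when scoring a replicate.

def _score_fit(fit, truth_coefs: dict) -> list[dict]:
    ci = fit.conf_int()
    rows = []
    for j, name in enumerate(fit.names):
        if name not in truth_coefs:
            continue
        true = truth_coefs[name]
        rows.append({
            "term": name, "true": true, "estimate": float(fit.beta[j]),
            "covered": bool(ci[j, 0] <= true <= ci[j, 1]),
            "significant": bool(fit.p[j] < 0.05),
        })
    return rows


def recovery_study(params: SimulationParams, n_reps: int = 100,
                   seed: int = 0,
                   config: PathConfig | None = None) -> pd.DataFrame:
    """Parameter recovery over repeated simulate -> path-analysis runs.

    Returns one row per (submodel, coefficient): true value, mean estimate,
    bias, RMSE and 95% CI coverage, plus one row per d-sep layer quantity
    (Fisher's C rejection rate at alpha = 0.05). Failed replicates are
    logged, excluded and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or PathConfig()
    rng = np.random.default_rng(seed)
    rows = []
    fisher_reject = 0
    failures = 0
    n_ok = 0
    for rep in range(n_reps):
        p = dc_replace(params, seed=int(rng.integers(2**31 - 1)))
        try:
            dataset, tree, truth = simulate_dataset(p)
            result = run_path_analysis(dataset, tree=tree, config=config)
        except Exception as exc:
            failures += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            continue
        n_ok += 1
        fisher_reject += int(result.fisher_p < 0.05)
        for key, truth_key in (("endemic", "endemic"), ("ploidy", "ploidy")):
            if key not in result.fits:
                continue
            for row in _score_fit(result.fits[key], truth[truth_key]):
                row["submodel"] = key
                row["rep"] = rep
                rows.append(row)
    if n_ok == 0:
        raise RuntimeError(f"all {n_reps} replicates failed")
    df = pd.DataFrame(rows)
    out = (df.groupby(["submodel", "term"], sort=False)
             .agg(true=("true", "first"),
                  mean_estimate=("estimate", "mean"),
                  coverage=("covered", "mean"),
                  power=("significant", "mean"),
                  n_reps=("estimate", "size"))
             .reset_index())
    out["bias"] = out["mean_estimate"] - out["true"]
    rmse = (df.assign(sq=(df.estimate - df.true) ** 2)
              .groupby(["submodel", "term"], sort=False)["sq"].mean()
              ** 0.5).reset_index(drop=True)
    out["rmse"] = rmse
    out.attrs["fisher_rejection_rate"] = fisher_reject / n_ok
    out.attrs["n_failures"] = failures
    out.attrs["n_ok"] = n_ok
    return out


def dsep_calibration(params: SimulationParams, n_reps: int = 200,
                     seed: int = 0) -> dict:
    """Calibration of the directed-separation layer under the diagram.

    Simulates data exactly under the causal diagram (continuous latent
    responses, so the tested model is correctly specified), runs only the
    d-sep tests plus Fisher's C each replicate, and reports per-claim p
    values and the global rejection rate at alpha = 0.05.
    """
    from .lineage_data import compute_weights
    from .path_sem import _default_specs, dsep_test, fishers_c

    rng = np.random.default_rng(seed)
    dag = island_dag()
    specs = _default_specs(PathConfig())
    claim_ps: dict[str, list[float]] = {}
    rejections = 0
    n_ok = 0
    for _ in range(n_reps):
        p = dc_replace(params, round_counts=False,
                       seed=int(rng.integers(2**31 - 1)))
        dataset, tree, _truth = simulate_dataset(p)
        ws, wp = compute_weights(dataset)
        cov = phylo_cov.brownian_cov(tree, tip_order=dataset.lineage_ids)
        claims = dsep_test(dag, dataset, cov.R, ws, wp, specs=specs)
        ps = [c.p_value for c in claims if c.p_value is not None]
        if len(ps) != len(claims):
            continue
        n_ok += 1
        for c in claims:
            claim_ps.setdefault(c.label(), []).append(c.p_value)
        _, _, global_p = fishers_c(ps)
        rejections += int(global_p < 0.05)
    return {
        "n_reps": n_ok,
        "rejection_rate": rejections / n_ok,
        "claim_p_values": {k: np.asarray(v) for k, v in claim_ps.items()},
    }
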