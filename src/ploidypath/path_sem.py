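"""Piecewise structural-equation model over the island-polyploidy causal diagram.

The causal diagram has four exogenous drivers (stem age, ploidy change at
colonization, source-pool size, repeat colonization coded as island
monophyly) and two endogenous responses (number of ploidy levels, endemic
diversity), linked by seven directed paths P1-P7:

    P1 PloidyLevels       -> EndemicDiversity
    P2 StemAge            -> PloidyLevels
    P3 PloidyChange       -> PloidyLevels
    P4 SourcePool         -> PloidyLevels
    P5 StemAge            -> EndemicDiversity
    P6 SourcePool         -> EndemicDiversity
    P7 RepeatColonization -> EndemicDiversity

Each endogenous response is fitted by weighted PGLS; the local fits are
united by tests of directed separation: every independence claim implied by
a missing edge is tested by adding the "missing" predictor to the local
regression of the claim's endogenous member, and the claim p values combine
into Fisher's C = -2 sum(ln p) ~ chi-square with 2k df under the diagram.

Archipelago is a covariate in every submodel and every d-sep regression,
not a node of the diagram: the diagram describes lineage-level causes while
island membership enters as fixed intercept/slope heterogeneity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .lineage_data import (ANALYSIS_ARCHIPELAGOS, AnalysisDataset,
                           compute_weights)
from .pgls_engine import (FitError, ModelSpec, PglsFit, Term, build_design,
                          endemic_spec, fit_weighted_pgls, ploidy_spec,
                          predictor_values, response_values)
from . import phylo_cov

logger = logging.getLogger("ploidypath")

ALPHA = 0.05

#: Diagram node -> analysis-scale variable (see :func:`node_column`).
NODE_VARIABLES = {
    "StemAge": "log_stem_age",
    "PloidyChange": "ploidy_change",
    "SourcePool": "source_pool",
    "RepeatColonization": "monophyletic",  # 1 = single colonization
    "PloidyLevels": "ploidy_levels",
    "EndemicDiversity": "log_endemic",
}

#: Endogenous node -> the submodel response key of its local regression.
RESPONSE_NODE = {"log_endemic": "EndemicDiversity",
                 "ploidy_levels": "PloidyLevels"}


# ---------------------------------------------------------------------------
# Causal diagram
# ---------------------------------------------------------------------------

@dataclass
class CausalDiagram:
    """A labeled DAG of lineage-level causes."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("causal diagram must be acyclic")
        labels = [d.get("label") for _, _, d in self.graph.edges(data=True)
                  if d.get("label")]
        if len(labels) != len(set(labels)):
            raise ValueError("edge labels must be unique")

    @property
    def nodes(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def exogenous(self) -> list[str]:
        return [v for v in self.nodes if self.graph.in_degree(v) == 0]

    def endogenous(self) -> list[str]:
        return [v for v in self.nodes if self.graph.in_degree(v) > 0]

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def edges(self) -> list[tuple[str, str, str]]:
        out = [(u, v, d.get("label", f"{u}->{v}"))
               for u, v, d in self.graph.edges(data=True)]
        order = {n: i for i, n in enumerate(self.nodes)}
        return sorted(out, key=lambda e: (order[e[1]], order[e[0]]))

    def with_edge(self, u: str, v: str, label: str) -> "CausalDiagram":
        g = self.graph.copy()
        g.add_edge(u, v, label=label)
        return CausalDiagram(g)


def island_dag() -> CausalDiagram:
    """The seven-path P1-P7 diagram (module docstring)."""
    g = nx.DiGraph()
    g.add_edge("StemAge", "PloidyLevels", label="P2")
    g.add_edge("PloidyChange", "PloidyLevels", label="P3")
    g.add_edge("SourcePool", "PloidyLevels", label="P4")
    g.add_edge("PloidyLevels", "EndemicDiversity", label="P1")
    g.add_edge("StemAge", "EndemicDiversity", label="P5")
    g.add_edge("SourcePool", "EndemicDiversity", label="P6")
    g.add_edge("RepeatColonization", "EndemicDiversity", label="P7")
    return CausalDiagram(g)


# ---------------------------------------------------------------------------
# Basis set and directed-separation tests
# ---------------------------------------------------------------------------

@dataclass
class IndependenceClaim:
    """One directed-separation claim: response _||_ added | conditioning."""

    response: str               # endogenous member (regression response)
    added: str                  # the "missing" predictor
    conditioning: tuple[str, ...]
    t: float | None = None
    p_value: float | None = None
    note: str = ""

    def label(self) -> str:
        cond = ", ".join(self.conditioning)
        return f"{self.added} _||_ {self.response} | {{{cond}}}"


def basis_set(dag: CausalDiagram) -> list[IndependenceClaim]:
    """Independence claims implied by the diagram's missing edges.

    One claim per non-adjacent node pair, excluding exogenous-exogenous
    pairs (their association is left free). The conditioning set is the
    union of both members' parents; the regression response is the pair
    member later in topological order (always endogenous). Claims are
    returned in a fixed topological order.
    """
    order = {n: i for i, n in enumerate(dag.nodes)}
    exo = set(dag.exogenous())
    g = dag.graph
    claims = []
    for i, u in enumerate(dag.nodes):
        for v in dag.nodes[i + 1:]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                continue
            if u in exo and v in exo:
                continue
            resp, added = (v, u) if order[v] > order[u] else (u, v)
            cond = sorted((set(dag.parents(u)) | set(dag.parents(v)))
                          - {u, v})
            claims.append(IndependenceClaim(response=resp, added=added,
                                            conditioning=tuple(cond)))
    claims.sort(key=lambda c: (order[c.response], order[c.added]))
    return claims


def node_column(dataset: AnalysisDataset, node: str,
                spec: ModelSpec) -> np.ndarray:
    """Analysis-scale values of a diagram node over the dataset."""
    var = NODE_VARIABLES[node]
    if var == "log_endemic":
        counts = np.asarray([r.n_endemic for r in dataset.records],
                            dtype=float)
        return np.log(counts)
    return predictor_values(dataset, var, spec)


def _weights_for_response(node: str, weights_species: np.ndarray,
                          weights_ploidy: np.ndarray) -> np.ndarray:
    return weights_species if node == "EndemicDiversity" else weights_ploidy


def dsep_test(dag: CausalDiagram, dataset: AnalysisDataset, R: np.ndarray,
              weights_species: np.ndarray, weights_ploidy: np.ndarray,
              specs: dict[str, ModelSpec] | None = None,
              spec_options: ModelSpec | None = None,
              variance_power: float = 1.0) -> list[IndependenceClaim]:
    """Test every basis-set claim by ML PGLS.

    For each claim the endogenous member is regressed on its conditioning
    set plus the added ("missing") node, with the same correlation matrix
    and the response-matched weights used by the corresponding submodel.
    When the response has a submodel spec in ``specs``, the claim reuses
    that submodel's full design (archipelago intercepts and by-archipelago
    slopes included) so the test inherits the submodel's island structure;
    the conditioning-set covariates are then exactly the submodel
    predictors. For responses without a spec (arbitrary diagrams) the
    design is intercept + archipelago contrasts + conditioning columns.
    The added term's two-sided p value is recorded; fit failures annotate
    the claim instead of aborting the suite.
    """
    opts = spec_options or ModelSpec(response="log_endemic", predictors=())
    spec_for_node = {}
    for spec in (specs or {}).values():
        spec_for_node[RESPONSE_NODE[spec.response]] = spec
    claims = basis_set(dag)
    archs = [r.archipelago for r in dataset.records]
    present = [a for a in ANALYSIS_ARCHIPELAGOS if a in set(archs)]
    ref = opts.reference if opts.reference in present else present[0]
    for claim in claims:
        try:
            spec = spec_for_node.get(claim.response)
            if spec is not None:
                X, y, terms = build_design(dataset, spec)
                added_var = NODE_VARIABLES[claim.added]
                names = [t.name for t in terms]
                if added_var in names:
                    j = names.index(added_var)
                else:
                    X = np.column_stack([X, node_column(dataset, claim.added,
                                                        spec)])
                    terms = terms + [Term(added_var, "continuous")]
                    j = X.shape[1] - 1
            else:
                cols = [np.ones(len(dataset))]
                terms = [Term("intercept", "intercept")]
                for a in present:
                    if a == ref:
                        continue
                    cols.append(np.asarray([1.0 if x == a else 0.0
                                            for x in archs]))
                    terms.append(Term(f"arch_{a}", "archipelago", arch=a))
                for node in claim.conditioning:
                    cols.append(node_column(dataset, node, opts))
                    terms.append(Term(node, "continuous"))
                cols.append(node_column(dataset, claim.added, opts))
                terms.append(Term(claim.added, "continuous"))
                X = np.column_stack(cols)
                y = node_column(dataset, claim.response, opts)
                j = X.shape[1] - 1
            w = _weights_for_response(claim.response, weights_species,
                                      weights_ploidy)
            fit = fit_weighted_pgls(X, y, R, w, method="ML", terms=terms,
                                    variance_power=variance_power)
            claim.t = float(fit.t[j])
            claim.p_value = float(fit.p[j])
        except FitError as exc:
            claim.note = f"fit failed: {exc}"
            logger.warning("d-sep claim %s: %s", claim.label(), exc)
    return claims


def fishers_c(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p values.

    ``C = -2 sum(ln p)`` compared against chi-square with ``2k`` df; an
    empty claim list gives (0, 0, 1). Zero p values are an error — callers
    should clamp to the machine minimum with a warning.
    """
    ps = list(p_values)
    if not ps:
        return 0.0, 0, 1.0
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p values must lie in (0, 1], got {p}")
    C = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * len(ps)
    return C, df, float(stats.chi2.sf(C, df))


# ---------------------------------------------------------------------------
# Standardization and goodness of fit
# ---------------------------------------------------------------------------

def standardize(fit: PglsFit, dataset: AnalysisDataset | None = None,
                ) -> pd.DataFrame:
    """Standardized coefficients: beta * SD(predictor) / SD(response).

    SDs are computed on the analysis scale over the fitted data. Binary
    predictors use the SD of the observed 0/1 indicator (flagged in the
    output); intercept and archipelago contrasts are omitted.
    """
    sd_y = float(np.std(fit.y, ddof=1))
    rows = []
    for j, t in enumerate(fit.terms):
        if t.kind in ("intercept", "archipelago"):
            continue
        sd_x = float(np.std(fit.X[:, j], ddof=1))
        if sd_x == 0.0:
            raise ValueError(f"zero-variance predictor {t.name!r}")
        rows.append({
            "term": t.name,
            "raw": float(fit.beta[j]),
            "standardized": float(fit.beta[j]) * sd_x / sd_y,
            "binary_sd_convention": t.kind == "binary",
        })
    return pd.DataFrame(rows)


def rsquared(fit: PglsFit, flavor: str = "corr") -> float:
    """Goodness of fit of one submodel.

    ``corr`` (default): squared Pearson correlation between fitted and
    observed response. ``pseudo``: likelihood-ratio pseudo-R^2,
    ``1 - exp(-(2/n) (logLik_model - logLik_0))``, against the intercept-only
    model with the same correlation matrix and weights.
    """
    if flavor == "corr":
        if np.std(fit.fitted) == 0.0:
            logger.warning("constant fitted values; R^2 reported as 0")
            return 0.0
        r = float(np.corrcoef(fit.fitted, fit.y)[0, 1])
        return r * r
    if flavor == "pseudo":
        n = len(fit.y)
        # Refit intercept-only with the same V (weights already inside V).
        w = np.ones(n)
        null = fit_weighted_pgls(np.ones((n, 1)), fit.y, fit.V, w,
                                 method="ML",
                                 terms=[Term("intercept", "intercept")])
        return 1.0 - math.exp(-(2.0 / n) * (fit.ml_loglik(fit._rss / n)
                                            - null.loglik_ml))
    raise ValueError(f"unknown R^2 flavor {flavor!r}")


# ---------------------------------------------------------------------------
# Full path analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathConfig:
    """Options threaded through the whole path analysis."""

    method: str = "REML"          # coefficient reporting; d-sep always ML
    reference: str = "NZ"
    log_ploidy: bool = False
    log_pool: bool = False
    variance_power: float = 1.0
    r2_flavor: str = "corr"


@dataclass
class PathAnalysisResult:
    """Submodel fits plus the directed-separation layer."""

    fits: dict[str, PglsFit]
    specs: dict[str, ModelSpec]
    path_table: pd.DataFrame
    island_effects: pd.DataFrame
    claims: list[IndependenceClaim]
    fisher_c: float
    fisher_df: int
    fisher_p: float
    r2: dict[str, float]
    config: PathConfig = field(default_factory=PathConfig)

    def to_dict(self) -> dict:
        return {
            "submodels": {k: f.to_dict() for k, f in self.fits.items()},
            "paths": self.path_table.to_dict("records"),
            "island_effects": self.island_effects.to_dict("records"),
            "dsep": {
                "claims": [{
                    "claim": c.label(), "t": c.t, "p": c.p_value,
                    "note": c.note,
                } for c in self.claims],
                "C": self.fisher_c, "df": self.fisher_df,
                "p": self.fisher_p,
            },
            "r2": self.r2,
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _default_specs(config: PathConfig) -> dict[str, ModelSpec]:
    kw = dict(reference=config.reference, log_ploidy=config.log_ploidy,
              log_pool=config.log_pool)
    return {"endemic": endemic_spec(**kw), "ploidy": ploidy_spec(**kw)}


#: Fig-style edge -> (submodel key, design term) for the path table.
EDGE_TERMS = {
    ("PloidyLevels", "EndemicDiversity"): ("endemic", "ploidy_levels"),
    ("StemAge", "EndemicDiversity"): ("endemic", "log_stem_age"),
    ("SourcePool", "EndemicDiversity"): ("endemic", "source_pool"),
    ("RepeatColonization", "EndemicDiversity"): ("endemic", "monophyletic"),
    ("StemAge", "PloidyLevels"): ("ploidy", "log_stem_age"),
    ("PloidyChange", "PloidyLevels"): ("ploidy", "ploidy_change"),
    ("SourcePool", "PloidyLevels"): ("ploidy", "source_pool"),
    ("PloidyChange", "EndemicDiversity"): ("endemic", "ploidy_change"),
    ("RepeatColonization", "PloidyLevels"): ("ploidy", "monophyletic"),
}


def _island_effects(fits: dict[str, PglsFit]) -> pd.DataFrame:
    """Archipelago intercept and slope heterogeneity, both parameterizations.

    ``deviation`` is the fitted contrast against the reference archipelago;
    ``cell`` adds the reference-level coefficient back (cell-means form),
    with its SE from the corresponding contrast of the coefficient
    covariance.
    """
    rows = []
    for key, fit in fits.items():
        names = fit.names
        cov = fit.cov_unscaled * fit.sigma2_resid
        for j, t in enumerate(fit.terms):
            if t.kind == "archipelago":
                rows.append({
                    "submodel": key, "effect": t.name, "arch": t.arch,
                    "kind": "intercept",
                    "deviation": float(fit.beta[j]),
                    "deviation_se": float(fit.se[j]),
                    "t": float(fit.t[j]), "p": float(fit.p[j]),
                    "cell": float(fit.beta[0] + fit.beta[j]),
                    "cell_se": math.sqrt(cov[0, 0] + cov[j, j]
                                         + 2 * cov[0, j]),
                })
            elif t.kind == "interaction":
                k = names.index(t.base)
                rows.append({
                    "submodel": key, "effect": t.name, "arch": t.arch,
                    "kind": "slope",
                    "deviation": float(fit.beta[j]),
                    "deviation_se": float(fit.se[j]),
                    "t": float(fit.t[j]), "p": float(fit.p[j]),
                    "cell": float(fit.beta[k] + fit.beta[j]),
                    "cell_se": math.sqrt(cov[k, k] + cov[j, j]
                                         + 2 * cov[k, j]),
                })
    return pd.DataFrame(rows)


def run_path_analysis(dataset: AnalysisDataset,
                      tree=None,
                      cov: "phylo_cov.CovarianceStructure | None" = None,
                      config: PathConfig | None = None,
                      dag: CausalDiagram | None = None,
                      specs: dict[str, ModelSpec] | None = None,
                      ) -> PathAnalysisResult:
    """Full pipeline: weights -> covariance -> submodels -> d-sep -> C -> R^2.

    Either a pruned dated tree or a precomputed covariance structure must be
    supplied; the covariance is aligned to the dataset's canonical record
    order. Any stage failure raises with the stage named.
    """
    config = config or PathConfig()
    dag = dag or island_dag()
    specs = specs or _default_specs(config)

    stage = "weights"
    try:
        if dataset.weights_species is None or dataset.weights_ploidy is None:
            ws, wp = compute_weights(dataset)
        else:
            ws, wp = dataset.weights_species, dataset.weights_ploidy

        stage = "covariance"
        if cov is None:
            if tree is None:
                raise ValueError("need a tree or a covariance structure")
            cov = phylo_cov.brownian_cov(tree, tip_order=dataset.lineage_ids)
        if cov.tip_order != dataset.lineage_ids:
            raise ValueError("covariance tip order does not match dataset")
        R = cov.R

        stage = "submodels"
        fits: dict[str, PglsFit] = {}
        for key, spec in specs.items():
            w = ws if spec.response == "log_endemic" else wp
            X, y, terms = build_design(dataset, spec)
            fits[key] = fit_weighted_pgls(
                X, y, R, w, method=config.method, terms=terms,
                variance_power=config.variance_power)

        stage = "dsep"
        opts = next(iter(specs.values()))
        claims = dsep_test(dag, dataset, R, ws, wp, specs=specs,
                           spec_options=opts,
                           variance_power=config.variance_power)
        ps = []
        for c in claims:
            if c.p_value is None:
                continue
            p = c.p_value
            if p <= 0.0:
                logger.warning("claim %s: p = 0 clamped to machine minimum",
                               c.label())
                p = np.finfo(float).tiny
            ps.append(p)
        C, df, global_p = fishers_c(ps)

        stage = "standardize"
        std = {k: standardize(f).set_index("term") for k, f in fits.items()}

        stage = "r2"
        r2 = {k: rsquared(f, config.r2_flavor) for k, f in fits.items()}

        stage = "path_table"
        rows = []
        for u, v, label in dag.edges():
            if (u, v) not in EDGE_TERMS:
                continue
            key, term = EDGE_TERMS[(u, v)]
            if key not in fits or term not in fits[key].names:
                continue
            fit = fits[key]
            j = fit.names.index(term)
            rows.append({
                "edge": label, "from": u, "to": v,
                "submodel": key, "term": term,
                "estimate": float(fit.beta[j]), "se": float(fit.se[j]),
                "t": float(fit.t[j]), "p": float(fit.p[j]),
                "standardized": float(std[key].loc[term, "standardized"]),
                "significant": bool(fit.p[j] < ALPHA),
            })
        path_table = pd.DataFrame(rows)
        island_effects = _island_effects(fits)
    except Exception as exc:
        raise RuntimeError(f"path analysis failed at stage "
                           f"{stage!r}: {exc}") from exc

    return PathAnalysisResult(
        fits=fits, specs=specs, path_table=path_table,
        island_effects=island_effects, claims=claims,
        fisher_c=C, fisher_df=df, fisher_p=global_p, r2=r2, config=config)
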