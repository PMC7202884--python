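"""Climate versus geography as predictors of evolutionary group membership.

Three complementary analyses:

* :func:`compare_classifiers` — random-forest classification of group
  labels from a climatic feature set (MAT, MAP, TS, CWD) versus a
  geographic one (continent, latitude, longitude), scored by
  out-of-bag accuracy with impurity (Gini) importances.  If climate
  out-predicts geography, niche conservatism is the better explanation
  of the grouping; the reverse supports dispersal limitation.
* :func:`rank_climate_variables` — within a super-group split into two
  labels, single-variable binomial regressions with a 1-degree
  grid-cell varying intercept (to absorb spatial autocorrelation),
  ranked by AIC.
* :func:`delimitation_correspondence` — agreement between a K = 2
  clustering and binary tropics delimitations (latitude band, freezing
  line, or user-supplied flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier

from .assemblages import CLIMATE_VARS, SiteCovariates

__all__ = [
    "ClassificationComparison",
    "DelimitationMatch",
    "compare_classifiers",
    "rank_climate_variables",
    "delimitation_correspondence",
    "fit_binomial_random_intercept",
]

log = logging.getLogger(__name__)

TROPIC_LATITUDE = 23.4  # degrees; the C1 latitudinal delimitation


@dataclass
class ClassificationComparison:
    model_id: str  # "climate" or "geography"
    features: list
    mean_accuracy: float  # out-of-bag accuracy
    per_class_accuracy: dict
    importances: dict  # feature -> mean decrease in Gini impurity (normalized)
    oob: bool
    seed: int
    n_sites: int


@dataclass
class DelimitationMatch:
    delimitation_id: str
    match_fraction: float  # best over the two cluster -> class mappings
    mapping: dict  # cluster label -> "tropical" / "extratropical"


def _oob_accuracy(rf: RandomForestClassifier, X, y):
    """Overall and per-class accuracy from out-of-bag votes."""
    votes = rf.oob_decision_function_
    ok = ~np.isnan(votes).any(axis=1)
    pred = rf.classes_[np.nanargmax(votes[ok], axis=1)]
    yo = np.asarray(y)[ok]
    overall = float((pred == yo).mean())
    per_class = {
        (c.item() if hasattr(c, "item") else c):
            float((pred[yo == c] == c).mean())
        for c in rf.classes_ if (yo == c).any()
    }
    return overall, per_class


def _fit_forest(X: pd.DataFrame, y, seed: int, n_trees: int):
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X.to_numpy(), np.asarray(y))
    return rf


def compare_classifiers(cov: SiteCovariates, labels, seed: int,
                        n_trees: int = 500):
    """Fit climate and geography random forests on the same sites.

    ``labels`` is a per-site group vector aligned with ``cov``.  Sites
    without a continent assignment are excluded from both models so the
    comparison is on identical data.  Returns
    (climate :class:`ClassificationComparison`, geography ditto).
    """
    cov.require(CLIMATE_VARS + ["lat", "lon", "continent"])
    df = cov.data.copy()
    df["_label"] = np.asarray(labels)
    usable = df["continent"].notna()
    for c in CLIMATE_VARS + ["lat", "lon"]:
        usable &= df[c].notna()
    dropped = int((~usable).sum())
    if dropped:
        log.info("excluding %d sites lacking covariates/continent", dropped)
    df = df[usable]
    y = df["_label"].to_numpy()

    X_clim = df[CLIMATE_VARS]
    geo = pd.DataFrame({
        "south_america": (df["continent"] == "South").astype(int),
        "lat": df["lat"],
        "lon": df["lon"],
    })

    out = []
    for model_id, X in (("climate", X_clim), ("geography", geo)):
        rf = _fit_forest(X, y, seed=seed, n_trees=n_trees)
        acc, per_class = _oob_accuracy(rf, X, y)
        out.append(ClassificationComparison(
            model_id=model_id,
            features=list(X.columns),
            mean_accuracy=acc,
            per_class_accuracy=per_class,
            importances=dict(zip(X.columns,
                                 rf.feature_importances_.tolist())),
            oob=True,
            seed=seed,
            n_sites=len(df),
        ))
    return tuple(out)


def fit_binomial_random_intercept(y, x, groups, n_quad: int = 25):
    """Logistic regression of a binary response on one standardized
    covariate with a per-group varying intercept.

    The random intercept is integrated out by Gauss-Hermite quadrature
    (groups are independent, so the marginal likelihood factorizes per
    group).  Returns (loglik, AIC, params dict).  With a single site
    per group everywhere the variance is unidentifiable and a plain
    logistic fit is used instead (logged).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    uniq, gidx = np.unique(groups, return_inverse=True)
    n_groups = len(uniq)
    max_size = int(np.bincount(gidx).max())

    def _glm():
        import statsmodels.api as sm
        X = sm.add_constant(x)
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return float(fit.llf), float(fit.aic), {
            "intercept": float(fit.params[0]), "slope": float(fit.params[1]),
            "sigma": 0.0,
        }

    if max_size == 1:
        log.info("one site per grid cell: falling back to plain "
                 "binomial regression")
        return _glm()

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    z = np.sqrt(2.0) * nodes  # standard-normal abscissae
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    def negll(theta):
        b0, b1, log_sigma = theta
        sigma = np.exp(log_sigma)
        # (n x Q) linear predictor with the random intercept offset
        e = (b0 + b1 * x)[:, None] + sigma * z[None, :]
        ll_obs = np.where(y[:, None] > 0,
                          -np.logaddexp(0.0, -e),
                          -np.logaddexp(0.0, e))
        # per-group log-likelihood at each quadrature node
        group_ll = np.empty((n_groups, n_quad))
        for q in range(n_quad):
            group_ll[:, q] = np.bincount(gidx, weights=ll_obs[:, q],
                                         minlength=n_groups)
        return -float(logsumexp(group_ll + logw, axis=1).sum())

    ll0, _, p0 = _glm()
    res = minimize(negll, x0=np.array([p0["intercept"], p0["slope"], -1.0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    ll = -float(res.fun)
    if ll < ll0 - 1e-6:  # GLM nested at sigma -> 0: never do worse
        ll = ll0
        params = p0
    else:
        params = {"intercept": float(res.x[0]), "slope": float(res.x[1]),
                  "sigma": float(np.exp(res.x[2]))}
    aic = -2.0 * ll + 2.0 * 3
    return ll, aic, params


def rank_climate_variables(cov: SiteCovariates, binary_labels,
                           grid: float = 1.0,
                           variables=None) -> pd.DataFrame:
    """AIC table for single climate variables predicting a binary split.

    Each candidate variable (default MAT, MAP, TS, CWD) is z-scored and
    fit as the sole fixed effect of a binomial regression with a
    varying intercept per ``grid``-degree grid cell (floor(lat), floor(lon)).
    Constant variables are skipped with a warning.  Returns the table
    sorted by AIC (best first) with a delta_aic column.
    """
    if variables is None:
        variables = list(CLIMATE_VARS)
    cov.require(list(variables) + ["lat", "lon"])
    y = np.asarray(binary_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("rank_climate_variables needs exactly two labels")
    y01 = (y == classes[1]).astype(float)
    cells = [
        f"{int(np.floor(la / grid))}_{int(np.floor(lo / grid))}"
        for la, lo in zip(cov.data["lat"], cov.data["lon"])
    ]
    rows = []
    for var in variables:
        x = cov.data[var].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            log.warning("variable %s is constant across sites; skipped", var)
            continue
        xz = (x - x.mean()) / sd
        ll, aic, params = fit_binomial_random_intercept(y01, xz, cells)
        rows.append({"variable": var, "aic": aic, "loglik": ll,
                     "slope": params["slope"], "sigma": params["sigma"]})
    tab = pd.DataFrame(rows).sort_values("aic", kind="stable")
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.reset_index(drop=True)


def delimitation_correspondence(cov: SiteCovariates, labels_k2,
                                delimitations=None):
    """Agreement between a K = 2 clustering and binary tropics
    delimitations.

    The latitude-band delimitation ("C1-latitude", |lat| <= 23.4) is
    computed internally; every other requested delimitation must exist
    as a 0/1 covariate column (1 = tropical side).  The match fraction
    maximizes over the two possible cluster -> {tropical, extratropical}
    mappings, so it is always >= 0.5.  Missing flags are skipped with a
    warning.
    """
    labels = np.asarray(labels_k2)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("delimitation correspondence needs K = 2 labels")
    if delimitations is None:
        delimitations = ["C1-latitude"] + [
            c for c in cov.data.columns
            if set(pd.unique(cov.data[c].dropna())) <= {0, 1, True, False}
            and c not in ("continent",)
        ]
    out = []
    for name in delimitations:
        if name == "C1-latitude":
            flag = (np.abs(cov.data["lat"].to_numpy()) <= TROPIC_LATITUDE)
        elif name in cov.data.columns:
            # delimitation flags mark the *extratropical* condition when
            # named for it (e.g. freezing); tropical = flag absent
            flag = ~(cov.data[name].to_numpy().astype(bool))
        else:
            log.warning("delimitation %s not in covariates; skipped", name)
            continue
        m0 = float((flag == (labels == uniq[0])).mean())
        m1 = float((flag == (labels == uniq[1])).mean())
        if m0 >= m1:
            mapping = {uniq[0].item() if hasattr(uniq[0], "item") else uniq[0]:
                       "tropical",
                       uniq[1].item() if hasattr(uniq[1], "item") else uniq[1]:
                       "extratropical"}
            frac = m0
        else:
            mapping = {uniq[0].item() if hasattr(uniq[0], "item") else uniq[0]:
                       "extratropical",
                       uniq[1].item() if hasattr(uniq[1], "item") else uniq[1]:
                       "tropical"}
            frac = m1
        out.append(DelimitationMatch(delimitation_id=name,
                                     match_fraction=frac, mapping=mapping))
    return out
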