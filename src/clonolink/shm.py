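"""Germline assignment, SHM quantification and class-switch models.

Somatic hypermutation is counted as V/J-region substitutions outside the
CDR3 against the nearest germline segment (maximal ungapped identity, ties
broken by reference name order); the combined rate divides the summed V and
J substitution counts by the sequence length excluding the CDR3.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logsumexp

from .config import ConfigurationError

log = logging.getLogger(__name__)

SWITCHED_ISOTYPES = ("IgG", "IgA")
UNSWITCHED_ISOTYPES = ("IgM", "IgD")

SHM_COLUMNS = [
    "cell_id", "v_call_assigned", "j_call_assigned", "v_shm", "j_shm",
    "v_identity", "j_identity", "len_excl_cdr3", "vj_shm_rate",
]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_ungapped(obs: np.ndarray, ref: np.ndarray) -> tuple[int, int]:
    """(matches, aligned_length) at the best ungapped offset."""
    short, long_ = (obs, ref) if len(obs) <= len(ref) else (ref, obs)
    best = -1
    for off in range(len(long_) - len(short) + 1):
        m = int((long_[off : off + len(short)] == short).sum())
        if m > best:
            best = m
    return best, len(short)


def _nearest(obs: np.ndarray, refs: list[tuple[str, np.ndarray]]) -> tuple[str, int, int]:
    """Best reference by identity; ties broken by name order (refs pre-sorted)."""
    best_name, best_matches, best_len, best_ident = None, 0, 1, -1.0
    for name, ref in refs:
        if len(ref) == len(obs):
            matches, aligned = int((ref == obs).sum()), len(obs)
        else:
            matches, aligned = _best_ungapped(obs, ref)
        ident = matches / aligned if aligned else 0.0
        if ident > best_ident:
            best_name, best_matches, best_len, best_ident = name, matches, aligned, ident
    return best_name, best_matches, best_len


def assign_germline(igh_chains: pd.DataFrame, reference: dict) -> pd.DataFrame:
    """Assign each IgH chain its nearest germline V and J and count substitutions.

    ``reference`` is ``{'V': {name: seq}, 'J': {name: seq}}`` (see
    :func:`clonolink.germline.load_reference_fasta`).  Chains need a full
    ``sequence`` (V region + CDR3 + J region) and ``cdr3_nt``; the CDR3 is
    located inside the sequence to delimit the V/J regions.
    """
    if not reference.get("V") or not reference.get("J"):
        raise ConfigurationError("germline reference must contain V and J segments")
    v_refs = [(name, _encode(reference["V"][name])) for name in sorted(reference["V"])]
    j_refs = [(name, _encode(reference["J"][name])) for name in sorted(reference["J"])]
    rows = []
    for chain in igh_chains.itertuples(index=False):
        seq = str(chain.sequence)
        cdr3 = str(chain.cdr3_nt)
        idx = seq.find(cdr3) if seq and cdr3 else -1
        if idx < 0:
            continue
        v_obs = _encode(seq[:idx])
        j_obs = _encode(seq[idx + len(cdr3):])
        v_name, v_matches, v_len = _nearest(v_obs, v_refs)
        j_name, j_matches, j_len = _nearest(j_obs, j_refs)
        v_shm = v_len - v_matches
        j_shm = j_len - j_matches
        len_excl = len(v_obs) + len(j_obs)
        rows.append({
            "cell_id": chain.cell_id,
            "v_call_assigned": v_name,
            "j_call_assigned": j_name,
            "v_shm": v_shm,
            "j_shm": j_shm,
            "v_identity": v_matches / v_len if v_len else np.nan,
            "j_identity": j_matches / j_len if j_len else np.nan,
            "len_excl_cdr3": len_excl,
            "vj_shm_rate": shm_rate(v_shm, j_shm, len_excl),
        })
    return pd.DataFrame(rows, columns=SHM_COLUMNS)


def shm_rate(v_shm: int, j_shm: int, len_excl_cdr3: int) -> float:
    """Combined V-J SHM rate: (v_shm + j_shm) / length excluding the CDR3."""
    if len_excl_cdr3 <= 0:
        raise ValueError("sequence length excluding CDR3 must be positive")
    return (v_shm + j_shm) / len_excl_cdr3


def classify_switch(igh_chains: pd.DataFrame) -> pd.DataFrame:
    """Isotype and class-switch state from the IgH constant-gene call.

    IGHG*/IGHA* are class-switched, IGHM/IGHD are not; IGHE and unknown
    constant calls are marked excluded (they enter no switch model).
    """
    c_call = igh_chains["c_call"].fillna("").astype(str)
    isotype = pd.Series("unknown", index=igh_chains.index)
    switched = pd.Series(pd.NA, index=igh_chains.index, dtype="boolean")
    for prefix, iso, sw in (("IGHG", "IgG", True), ("IGHA", "IgA", True),
                            ("IGHM", "IgM", False), ("IGHD", "IgD", False),
                            ("IGHE", "IgE", pd.NA)):
        mask = c_call.str.startswith(prefix)
        isotype[mask] = iso
        switched[mask] = sw
    excluded = switched.isna()
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} cells with IgE/unknown isotype excluded "
                      "from switch models", stacklevel=2)
    return pd.DataFrame({"cell_id": igh_chains["cell_id"].to_numpy(),
                         "isotype": isotype.to_numpy(),
                         "switched": switched.to_numpy(dtype=object),
                         "excluded": excluded.to_numpy()})


def _effect_frame(names, est, se, pvals, reference_level):
    ci = 1.959963984540054 * np.asarray(se)
    df = pd.DataFrame({
        "level": names,
        "estimate": est,
        "se": se,
        "ci_low": np.asarray(est) - ci,
        "ci_high": np.asarray(est) + ci,
        "p_value": pvals,
    })
    ref_row = pd.DataFrame([{"level": reference_level, "estimate": 0.0, "se": 0.0,
                             "ci_low": 0.0, "ci_high": 0.0, "p_value": np.nan}])
    return pd.concat([ref_row, df], ignore_index=True)


def _dummies(series: pd.Series, reference: str) -> pd.DataFrame:
    levels = [l for l in sorted(series.unique()) if l != reference]
    if reference not in set(series):
        raise ConfigurationError(f"reference level {reference!r} absent from data")
    return pd.DataFrame({lv: (series == lv).astype(float).to_numpy() for lv in levels},
                        index=series.index)


def fit_shm_model(
    shm_records: pd.DataFrame,
    cells: pd.DataFrame,
    reference_subset: str,
    covariate: str = "subset",
) -> pd.DataFrame:
    """Linear model of vj_shm_rate with a donor random intercept.

    ``covariate`` 'subset' contrasts every subset against
    ``reference_subset``; 'tissue-within-subset' fits a SYN-vs-PBL contrast
    separately for each subset.  Returns an effect table with Wald 95% CIs.
    With a single donor the random intercept is degenerate, so an ordinary
    least-squares fit is used with a warning.
    """
    data = shm_records.merge(
        cells[["cell_id", "subset", "tissue", "donor_id"]], on="cell_id"
    )
    if covariate == "subset":
        return _fit_lmm(data, "vj_shm_rate", _dummies(data["subset"], reference_subset),
                        data["donor_id"], reference_subset)
    if covariate == "tissue-within-subset":
        frames = []
        for subset, grp in data.groupby("subset", sort=True):
            if grp["tissue"].nunique() < 2:
                continue
            tab = _fit_lmm(grp, "vj_shm_rate", _dummies(grp["tissue"], "PBL"),
                           grp["donor_id"], "PBL")
            tab.insert(0, "subset", subset)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    raise ValueError(f"unknown covariate {covariate!r}")


def _fit_lmm(data, endog_col, dummies, groups, reference_level) -> pd.DataFrame:
    endog = data[endog_col].to_numpy(dtype=float)
    exog = sm.add_constant(dummies.to_numpy())
    names = list(dummies.columns)
    if groups.nunique() < 2:
        warnings.warn("single donor: falling back to fixed-effects OLS", stacklevel=2)
        fit = sm.OLS(endog, exog).fit()
        return _effect_frame(names, fit.params[1:], fit.bse[1:], fit.pvalues[1:],
                             reference_level)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are expected
        model = sm.MixedLM(endog, exog, groups=np.asarray(groups))
        fit = model.fit(reml=True, method="lbfgs")
    k = exog.shape[1]
    return _effect_frame(names, fit.params[1:k], fit.bse[1:k], fit.pvalues[1:k],
                         reference_level)


def _glmm_logit_gh(endog, exog, groups, n_quad: int = 25):
    """Random-intercept logistic GLMM by Gauss-Hermite quadrature ML.

    Maximizes the marginal likelihood with the donor intercept integrated out
    numerically (the lme4-style nAGQ route); Wald SEs from the inverse
    observed information of the profile over (beta, log sigma).
    Returns (beta, se_beta).
    """
    from scipy.optimize import minimize
    from scipy.special import roots_hermite

    y = np.asarray(endog, dtype=float)
    x = np.asarray(exog, dtype=float)
    codes = pd.factorize(groups)[0]
    n_groups = codes.max() + 1
    p = x.shape[1]
    nodes, weights = roots_hermite(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    sign = 2.0 * y - 1.0

    def nll(params):
        beta, log_sigma = params[:p], params[p]
        sigma = np.exp(log_sigma)
        eta = x @ beta
        # per-observation loglik at each node: (n, K)
        z = sign[:, None] * (eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :])
        obs = -np.logaddexp(0.0, -z)
        per_group = np.zeros((n_groups, n_quad))
        np.add.at(per_group, codes, obs)
        group_ll = logsumexp(per_group + log_w[None, :], axis=1)
        return -group_ll.sum()

    try:
        start_beta = sm.Logit(y, x).fit(disp=0, maxiter=200).params
        if not np.all(np.isfinite(start_beta)):
            raise np.linalg.LinAlgError
    except Exception:  # separation: fall back to a crude but finite start
        start_beta = np.zeros(p)
        start_beta[0] = np.log((y.mean() + 1e-3) / (1 - y.mean() + 1e-3))
    start = np.append(start_beta, np.log(0.3))
    res = minimize(nll, start, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    theta = res.x
    # central-difference observed information
    k = len(theta)
    h = np.maximum(np.abs(theta), 1.0) * 1e-4
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    return theta[:p], se


def fit_switch_model(
    switch_states: pd.DataFrame,
    cells: pd.DataFrame,
    reference_subset: str,
    reference_tissue: str = "PBL",
) -> pd.DataFrame:
    """Mixed-effect logistic regression of class-switch state (log-odds scale).

    Fixed effects for subset (vs ``reference_subset``) and tissue (vs
    ``reference_tissue``); donor random intercept integrated out by
    Gauss-Hermite quadrature maximum likelihood, with Wald 95% CIs.  Subsets
    with all-0 or all-1 outcomes are reported with a separation warning.
    """
    data = switch_states[~switch_states["excluded"]].merge(
        cells[["cell_id", "subset", "tissue", "donor_id"]], on="cell_id"
    )
    data = data.reset_index(drop=True)
    for subset, grp in data.groupby("subset"):
        mean = grp["switched"].astype(float).mean()
        if mean in (0.0, 1.0):
            warnings.warn(
                f"complete separation: subset {subset!r} is all-"
                f"{'switched' if mean == 1.0 else 'unswitched'}", stacklevel=2)
    sub_dum = _dummies(data["subset"], reference_subset)
    tis_dum = _dummies(data["tissue"], reference_tissue)
    tis_dum.columns = [f"tissue[{c}]" for c in tis_dum.columns]
    exog = pd.concat([sub_dum, tis_dum], axis=1)
    exog_arr = sm.add_constant(exog.to_numpy())
    endog = data["switched"].astype(float).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est_all, se_all = _glmm_logit_gh(endog, exog_arr, data["donor_id"])
    k = exog_arr.shape[1]
    est = est_all[1:k]
    se = se_all[1:k]
    from scipy import stats as _st
    z = est / np.where(se > 0, se, np.nan)
    pvals = 2 * _st.norm.sf(np.abs(z))
    tab = _effect_frame(list(exog.columns), est, se, pvals,
                        reference_subset)
    tab["scale"] = "log-odds"
    return tab
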