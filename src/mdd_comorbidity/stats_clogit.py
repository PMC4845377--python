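"""Conditional logistic regression for 1:1 matched pairs.

For 1:1 matched sets the conditional likelihood reduces to intercept-free
logistic regression on within-pair covariate differences d_j = x_case - x_control:

    L(beta) = prod_j  exp(beta.x_case_j) / (exp(beta.x_case_j) + exp(beta.x_control_j))
            = prod_j  expit(beta . d_j)

Concordant pairs (d_j = 0) contribute a constant factor 1/2 and carry no
information.  The likelihood is maximized by Newton-Raphson with
step-halving; Wald 95% confidence intervals come from the inverse observed
information.  For a single binary exposure the maximum-likelihood odds ratio
equals the discordant-pair ratio n10/n01, which serves as an independent
closed-form check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ascertainment import AnalysisRow, prevalence_filter
from .catalog import ConditionCatalog
from .synthetic_ehr import EDUCATION_LEVELS

# Dummy contrasts vs the reference level (high school or less); "unknown"
# is kept as a modeled level rather than dropped.
EDUCATION_DUMMIES = EDUCATION_LEVELS[1:]


class DegenerateDesignError(ValueError):
    """All pairs concordant, or a covariate constant across difference vectors."""


@dataclass
class PairedDesign:
    differences: np.ndarray          # (n_pairs, p) case-minus-control
    covariate_names: list[str]

    def __post_init__(self):
        self.differences = np.asarray(self.differences, dtype=float)
        if self.differences.ndim == 1:
            self.differences = self.differences[:, None]

    @property
    def n_pairs(self) -> int:
        return self.differences.shape[0]

    @property
    def n_informative(self) -> int:
        return int(np.any(self.differences != 0, axis=1).sum())


@dataclass
class ClogitFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariate_names: list[str]
    converged: bool
    n_iterations: int
    log_likelihood: float
    message: str = ""

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> np.ndarray:
        with np.errstate(over="ignore"):  # separated fits legitimately hit inf
            lo = np.exp(self.coefficients - 1.96 * self.standard_errors)
            hi = np.exp(self.coefficients + 1.96 * self.standard_errors)
        return np.column_stack([lo, hi])

    def wald_p(self) -> np.ndarray:
        from scipy import stats

        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))


def _education_contrast(level: str) -> np.ndarray:
    vec = np.zeros(len(EDUCATION_DUMMIES))
    if level != EDUCATION_LEVELS[0]:
        vec[EDUCATION_DUMMIES.index(level)] = 1.0
    return vec


def build_design(
    rows: list[AnalysisRow],
    condition_id: str,
    adjusters: bool = True,
) -> PairedDesign:
    """Within-pair difference design for one condition (optionally adjusted).

    Covariates: the condition flag, then obesity and four education dummies
    (reference: high school or less) when ``adjusters`` is True.
    """
    by_pair: dict[str, dict[int, AnalysisRow]] = {}
    for r in rows:
        by_pair.setdefault(r.pair_id, {})[r.outcome] = r

    names = [condition_id]
    if adjusters:
        names += ["obesity"] + [f"education_{lvl}" for lvl in EDUCATION_DUMMIES]

    diffs = []
    for pair_id, members in by_pair.items():
        if set(members) != {0, 1}:
            raise ValueError(f"incomplete pair {pair_id}")
        case, control = members[1], members[0]

        def features(row: AnalysisRow) -> np.ndarray:
            x = [float(row.conditions[condition_id])]
            if adjusters:
                x.append(float(row.obesity))
                x.extend(_education_contrast(row.education))
            return np.asarray(x)

        diffs.append(features(case) - features(control))
    return PairedDesign(differences=np.asarray(diffs), covariate_names=names)


def fit_clogit(
    design: PairedDesign,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 15.0,
) -> ClogitFit:
    """Newton-Raphson fit of the paired conditional likelihood.

    Step-halving guards against non-increasing likelihood steps; separation
    (coefficients running off to +/-inf) is reported as non-converged rather
    than silently returning huge odds ratios.
    """
    D = design.differences
    informative = np.any(D != 0, axis=1)
    if not informative.any():
        raise DegenerateDesignError("all pairs concordant: no information")
    D = D[informative]
    zero_cols = ~np.any(D != 0, axis=0)
    if zero_cols.any():
        # zero-variance covariates make the information singular
        zero = [n for n, z in zip(design.covariate_names, zero_cols) if z]
        raise DegenerateDesignError(f"covariates with no within-pair variation: {zero}")

    p = D.shape[1]
    beta = np.zeros(p)

    def loglik(b):
        eta = D @ b
        return float(-np.logaddexp(0.0, -eta).sum())

    ll = loglik(beta)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = D @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = D.T @ (1.0 - mu)
        W = mu * (1.0 - mu)
        info = D.T @ (D * W[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving: retreat until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll = loglik(new_beta)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll = new_beta, new_ll
        if np.max(np.abs(beta)) > separation_bound:
            message = "separation suspected: coefficient diverging"
            break
        if np.max(np.abs(grad)) < tol:
            converged = True
            break

    eta = D @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = D.T @ (D * (mu * (1.0 - mu))[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return ClogitFit(
        coefficients=beta,
        standard_errors=se,
        covariate_names=list(design.covariate_names),
        converged=converged,
        n_iterations=it,
        log_likelihood=ll,
        message=message,
    )


def per_condition_analysis(
    rows: list[AnalysisRow],
    stratum: str,
    catalog: ConditionCatalog,
    threshold: float = 0.01,
    adjusters: bool = True,
):
    """Fit one adjusted conditional-logistic model per prevalent condition.

    Returns ``(results, not_analyzed)``: a list of per-condition dicts
    (odds ratio, Wald CI, informative-pair count, convergence flag) and the
    ids of conditions below the prevalence threshold or with degenerate
    designs.  Fit failures are recorded per condition, never abort the batch.
    """
    stratum_rows = [r for r in rows if r.stratum == stratum]
    if not stratum_rows:
        raise ValueError(f"no rows in stratum {stratum!r}")
    keep = prevalence_filter(stratum_rows, catalog.condition_ids, threshold)
    results = []
    not_analyzed = [
        {"condition_id": cid, "reason": "below_prevalence_threshold"}
        for cid in catalog.condition_ids
        if cid not in keep
    ]
    for cid in keep:
        try:
            design = build_design(stratum_rows, cid, adjusters=adjusters)
            active = np.any(design.differences != 0, axis=0)
            if not active[0]:
                raise DegenerateDesignError("no discordant pairs for condition")
            if not active.all():
                # adjusters concordant in every pair carry no information; drop them
                design = PairedDesign(
                    differences=design.differences[:, active],
                    covariate_names=[n for n, a in zip(design.covariate_names, active) if a],
                )
            fit = fit_clogit(design)
        except DegenerateDesignError as err:
            not_analyzed.append({"condition_id": cid, "reason": str(err)})
            continue
        results.append(
            {
                "stratum": stratum,
                "condition_id": cid,
                "or": float(fit.odds_ratio[0]),
                "ci_low": float(fit.ci95[0, 0]),
                "ci_high": float(fit.ci95[0, 1]),
                "n_informative": design.n_informative,
                "converged": fit.converged,
            }
        )
    return results, not_analyzed
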