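"""Bundled case-study reference values.

The real multi-jurisdiction EMR data behind the case study cannot be
redistributed; what ships instead are the *printed* regional, global,
meta-analysis and federated-likelihood results, so the pooling and RPAB
arithmetic can be reproduced exactly.  Loaders below turn the fixture into
the package's own types.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .federation import FederatedResult
from .glm_core import LocalFit
from .meta_analysis import StudyEstimate

__all__ = [
    "load_reference_tables",
    "reference_studies",
    "reference_global_fit",
    "reference_federated_results",
    "reference_meta_results",
]

PARAMETERS = ("intercept", "hypertension", "sex", "age")


def load_reference_tables() -> dict:
    """Raw fixture: printed regional/global coefficients, combined-likelihood
    estimates and the published summary table."""
    with resources.files("fedlik").joinpath("paper_tables.json").open() as fh:
        return json.load(fh)


def reference_studies(parameter: str, tables: dict | None = None) -> list[StudyEstimate]:
    """Regional estimate/SE pairs for one parameter, as meta-analysis input."""
    tables = tables or load_reference_tables()
    j = tables["parameters"].index(parameter)
    return [
        StudyEstimate(
            label=region,
            estimate=tables["regional_models"][region]["estimates"][j],
            se=tables["regional_models"][region]["se"][j],
        )
        for region in tables["regions"]
    ]


def reference_global_fit(tables: dict | None = None) -> LocalFit:
    """The pooled-data (global) model as printed, wrapped as a LocalFit."""
    tables = tables or load_reference_tables()
    g = tables["regional_models"]["Global"]
    return LocalFit(
        site_id="Global",
        parameter_names=PARAMETERS,
        estimates=np.array(g["estimates"]),
        standard_errors=np.array(g["se"]),
        ci_lower=np.array(tables["summary"]["global"]["ci_lower"]),
        ci_upper=np.array(tables["summary"]["global"]["ci_upper"]),
        max_loglik=tables["likelihood_models"]["max_loglik"]["Global"],
        converged=True,
        n_iterations=0,
        n=tables["site_n"]["Global"],
    )


def reference_meta_results(tables: dict | None = None) -> dict:
    """Printed common-effect summary rows wrapped as MetaResult objects.

    The pooled estimates and intervals are the published (4-decimal) values;
    weights and the heterogeneity statistics are recomputed around them from
    the regional rows.  Re-pooling from the regional rows instead agrees
    with the printed hypertension value at 4-decimal rounding (0.264556).
    """
    from scipy import stats as _stats

    from .meta_analysis import MetaResult, cochran_q, heterogeneity_p, i_squared

    tables = tables or load_reference_tables()
    ce = tables["summary"]["common_effect"]
    out = {}
    z = _stats.norm.ppf(0.975)
    for j, name in enumerate(tables["parameters"]):
        studies = reference_studies(name, tables)
        pooled = ce["estimates"][j]
        ci = (ce["ci_lower"][j], ce["ci_upper"][j])
        Q = cochran_q(studies, pooled)
        k = len(studies)
        out[name] = MetaResult(
            pooled=pooled,
            pooled_se=(ci[1] - ci[0]) / (2 * z),
            ci=ci,
            level=0.95,
            labels=tuple(s.label for s in studies),
            weights=np.array([1.0 / s.se**2 for s in studies]),
            Q=Q,
            df=k - 1,
            p_heterogeneity=heterogeneity_p(Q, k - 1),
            i_squared=i_squared(Q, k),
        )
    return out


def reference_federated_results(tables: dict | None = None) -> list[FederatedResult]:
    """The printed combined-likelihood estimates at increments 0.01 and
    0.005, wrapped as FederatedResult containers."""
    tables = tables or load_reference_tables()
    out = []
    for inc in (0.01, 0.005):
        key = f"likelihood_{inc:g}"
        row = tables["summary"][key]
        out.append(
            FederatedResult(
                parameter_names=PARAMETERS,
                estimates=np.array(row["estimates"]),
                likelihood_intervals=np.column_stack(
                    (row["li_lower"], row["li_upper"])
                ),
                combined_max_loglik=tables["likelihood_models"]["max_loglik"][
                    f"increment_{inc:g}"
                ]["Combined"],
                increment=inc,
                threshold=0.147,
                n_sites=len(tables["regions"]),
                total_n=tables["site_n"]["Global"],
            )
        )
    return out
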