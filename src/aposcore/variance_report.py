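"""Posterior variance decomposition and report assembly.

Two complementary R-squared measures are reported for the binomial model:

* **Bayes R²** — per posterior draw *s*, with fitted counts
  ``yhat_is = n_i * inv-logit(eta_is)`` and residuals
  ``e_is = y_i - yhat_is``,

      R²_s = Var_i(yhat_is) / (Var_i(yhat_is) + Var_i(e_is)),

  summarized over draws (the residual-draw definition, on the count
  scale).  A latent-scale variant is available behind a flag.

* **Marginal (fixed-effect) R²** — on the latent logit scale, per draw,

      marginal = Var_i(x_i beta) / (Var_i(x_i beta) + sigma² + π²/3),

  with π²/3 the logit link's distribution-specific variance; the share
  with sigma² in the numerator is the phylogenetic share.  "Phylogeny
  responsible for the remaining variation" is reported as this
  ``phylo_share``, not as the difference of the two R² values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .bayes_glmm import ModelData, PosteriorDraws, summarize

__all__ = [
    "R2Summary",
    "bayes_r2",
    "bayes_r2_from_fitted",
    "marginal_r2",
    "genus_effects",
    "build_report",
]

LOGIT_RESIDUAL_VAR = np.pi**2 / 3.0


@dataclass
class R2Summary:
    """Posterior summary of a proportion-of-variance statistic."""

    mean: float
    l95: float
    u95: float
    draws: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError("R2 summaries must lie in [0, 1]")


def _eta_draws(draws: PosteriorDraws, data: ModelData) -> np.ndarray:
    s = draws.stacked()
    return s["beta"] @ data.X.T + s["u"][:, data.species_idx]


def _summary(r2: np.ndarray) -> R2Summary:
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return R2Summary(float(r2.mean()), float(lo), float(hi), r2)


def bayes_r2_from_fitted(yhat: np.ndarray, y: np.ndarray) -> R2Summary:
    """Residual-draw Bayes R² from fitted values ``yhat`` (draws, n)."""
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    e = np.asarray(y, dtype=float)[None, :] - yhat
    var_fit = yhat.var(axis=1, ddof=1)
    var_res = e.var(axis=1, ddof=1)
    denom = var_fit + var_res
    r2 = np.divide(var_fit, denom, out=np.zeros_like(var_fit), where=denom > 0)
    return _summary(r2)


def bayes_r2(
    draws: PosteriorDraws, data: ModelData, scale: str = "response"
) -> R2Summary:
    """Bayes R² of the fitted binomial model.

    ``scale='response'`` (default) computes fitted counts n*p per draw;
    ``scale='latent'`` uses the linear predictor with the logit residual
    variance π²/3 in the denominator.
    """
    eta = _eta_draws(draws, data)
    if scale == "response":
        yhat = data.n[None, :] * expit(eta)
        return bayes_r2_from_fitted(yhat, data.y)
    if scale == "latent":
        var_fit = eta.var(axis=1, ddof=1)
        return _summary(var_fit / (var_fit + LOGIT_RESIDUAL_VAR))
    raise ValueError("scale must be 'response' or 'latent'")


def marginal_r2(
    draws: PosteriorDraws, data: ModelData
) -> tuple[R2Summary, R2Summary]:
    """Latent-scale fixed-effect R² and phylogenetic share, per draw.

    Returns ``(marginal, phylo_share)``; for every draw
    ``marginal + phylo_share <= 1``.
    """
    s = draws.stacked()
    var_f = (s["beta"] @ data.X.T).var(axis=1, ddof=1)
    sigma2 = s["sigma"] ** 2
    denom = var_f + sigma2 + LOGIT_RESIDUAL_VAR
    return _summary(var_f / denom), _summary(sigma2 / denom)


def genus_effects(draws: PosteriorDraws, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Mean posterior species effect aggregated to genus, ranked.

    ``taxonomy`` maps ``species_id`` to ``genus``; every modelled species
    must be mapped.  The genus effect is the mean of its member species'
    posterior-mean random effects, on the log-odds scale.
    """
    tax = taxonomy.set_index("species_id")["genus"]
    unmapped = [s for s in draws.species if s not in tax.index]
    if unmapped:
        raise KeyError(f"species without genus in taxonomy: {unmapped}")
    u_mean = pd.Series(
        draws.stacked()["u"].mean(axis=0), index=draws.species, name="u"
    )
    out = (
        u_mean.groupby(tax.loc[u_mean.index].to_numpy())
        .agg(mean_u="mean", n_species="size")
        .reset_index(names="genus")
        .sort_values("mean_u", ascending=False, ignore_index=True)
    )
    out["direction"] = np.sign(out["mean_u"]).astype(int)
    return out


def build_report(
    model_summaries: dict[int, pd.DataFrame],
    r2: dict[int, dict[str, object]] | None = None,
    qc=None,
    score_table: pd.DataFrame | None = None,
    genus_table: pd.DataFrame | None = None,
) -> str:
    """Assemble the run report as a markdown-style text document.

    ``model_summaries`` maps model number to its posterior summary table;
    a missing model is noted rather than an error.  ``score_table``
    (per-image cryptic scores) is emitted sorted by increasing detection
    time, the ordering used for the figure panels.
    """
    lines = ["# Detectability vs toxicity — run report", ""]
    for m in (1, 2):
        lines.append(f"## Model {m}")
        if m in model_summaries:
            lines.append(model_summaries[m].to_string(index=False))
        else:
            lines.append("(not fitted in this run)")
        if r2 and m in r2:
            block = r2[m]
            lines.append("")
            for key, val in block.items():
                if isinstance(val, R2Summary):
                    lines.append(
                        f"{key}: {val.mean:.3f} (95% CI {val.l95:.3f}-{val.u95:.3f})"
                    )
                else:
                    lines.append(f"{key}: {val}")
        lines.append("")
    if qc is not None:
        lines += [
            "## Quality control",
            f"rounds in: {qc.n_rounds_in}, kept: {qc.n_rounds_kept}",
            f"users in: {qc.n_users_in}, excluded: {qc.n_users_excluded}",
            f"mean found per game: {qc.mean_found_per_game:.2f}",
            "",
        ]
    if score_table is not None:
        ordered = score_table.sort_values("cryptic_time", ignore_index=True)
        lines += [
            "## Images by increasing most-cryptic detection time",
            ordered.to_string(index=False),
            "",
        ]
    if genus_table is not None:
        lines += ["## Genus effects on toxicity (log-odds)",
                  genus_table.to_string(index=False), ""]
    lines.append(
        "Marginal R2 uses the latent-logit decomposition with pi^2/3 as the "
        "link's residual variance; Bayes R2 uses residual draws on the "
        "count scale."
    )
    return "\n".join(lines)
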