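"""Ready-made population models for tutorials, tests and benchmarking.

Two standard study designs of the latent-moderation literature:

* a simple latent moderation model — two correlated predictors, one outcome,
  one interaction effect whose variance increment is 1.25% of the outcome
  variance (a realistic size for moderation effects in applied work);
* a moderated mediation model — the mediation ``xi2 -> eta1 -> eta2`` with
  ``xi1`` moderating both paths into ``eta2``; residual variances chosen so
  every latent has unit variance, giving variance increments of 1.25%
  (``xi1 xi2``) and 2.85% (``eta1 xi1``).

Loadings are all 1; the measurement-error variance sets the per-item
reliability: ``high`` means .8 (theta = .25), ``low`` means .5 (theta = 1).
"""

from __future__ import annotations

from .model_syntax import ModelSpec, parse_model

__all__ = [
    "moderation_model_text",
    "moderation_model",
    "moderated_mediation_model_text",
    "moderated_mediation_model",
    "RELIABILITY_THETA",
]

RELIABILITY_THETA = {"high": 0.25, "low": 1.0, "perfect": 0.0}


def _theta(reliability: str | float) -> float:
    if isinstance(reliability, str):
        try:
            return RELIABILITY_THETA[reliability]
        except KeyError:
            raise ValueError(
                f"unknown reliability {reliability!r}; use one of "
                f"{sorted(RELIABILITY_THETA)} or a numeric error variance"
            ) from None
    return float(reliability)


def _measurement(latent: str, indicators: list[str], theta: float) -> str:
    lines = [f"{latent} =~ " + " + ".join(f"1*{i}" for i in indicators)]
    lines += [f"{i} ~~ {theta}*{i}" for i in indicators]
    return "\n".join(lines)


def moderation_model_text(reliability: str | float = "high") -> str:
    """Simple latent moderation model: ``Eta1 ~ Xi1 + Xi2 + Xi1:Xi2``.

    The interaction coefficient is .1 and the residual variance .5975, so the
    moderation contributes 1.25% of the unit outcome variance.
    """
    theta = _theta(reliability)
    return "\n".join(
        [
            "# simple latent moderation model",
            _measurement("Xi1", ["x1", "x2", "x3"], theta),
            _measurement("Xi2", ["x4", "x5", "x6"], theta),
            _measurement("Eta1", ["y1", "y2", "y3"], theta),
            "Eta1 ~ 0.2*Xi1 + 0.5*Xi2 + 0.1*Xi1:Xi2",
            "Xi1 ~~ 1*Xi1",
            "Xi2 ~~ 1*Xi2",
            "Xi1 ~~ 0.5*Xi2",
            "Eta1 ~~ 0.5975*Eta1",
        ]
    )


def moderation_model(reliability: str | float = "high") -> ModelSpec:
    return parse_model(moderation_model_text(reliability))


def moderated_mediation_model_text(reliability: str | float = "high") -> str:
    """Moderated mediation model with two interaction effects.

    ``eta1 = .2 xi1 + .5 xi2 + zeta1`` and
    ``eta2 = .2 eta1 + .1 eta1 xi1 + .2 xi1 + .3 xi2 + .1 xi1 xi2 + zeta2``,
    all latents unit variance, predictors correlated .5; hence
    ``Var zeta1 = .61`` and ``Var zeta2 = .620975``.
    """
    theta = _theta(reliability)
    return "\n".join(
        [
            "# moderated mediation model",
            _measurement("Xi1", ["x1", "x2", "x3"], theta),
            _measurement("Xi2", ["x4", "x5", "x6"], theta),
            _measurement("Eta1", ["y1", "y2", "y3"], theta),
            _measurement("Eta2", ["y4", "y5", "y6"], theta),
            "Eta1 ~ 0.2*Xi1 + 0.5*Xi2",
            "Eta2 ~ 0.2*Eta1 + 0.1*Eta1:Xi1 + 0.2*Xi1 + 0.3*Xi2 + 0.1*Xi1:Xi2",
            "Xi1 ~~ 1*Xi1",
            "Xi2 ~~ 1*Xi2",
            "Xi1 ~~ 0.5*Xi2",
            "Eta1 ~~ 0.61*Eta1",
            "Eta2 ~~ 0.620975*Eta2",
        ]
    )


def moderated_mediation_model(reliability: str | float = "high") -> ModelSpec:
    return parse_model(moderated_mediation_model_text(reliability))
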