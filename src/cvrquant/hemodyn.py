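"""Davis-type forward model of the hypercapnic BOLD response.

The fractional BOLD signal change elicited by a CBF increase is modeled by
the calibrated-BOLD power law

    dBOLD/BOLD0 = k * CBV0 * [dHb]0^beta * (1 - (CBF_HC / CBF_0)^(alpha - beta))

where CBV0 is baseline venous blood volume, [dHb]0 the baseline
deoxyhemoglobin content (proportional to 1 - Yv0), alpha the flow-volume
power-law exponent and beta the field/voxel-size exponent (alpha < beta, so
a flow increase gives a positive response). The lumped constant k is
unidentifiable from a single measurement and defaults to 1.

Dividing by the end-tidal CO2 rise predicts BOLD-CVR in %/mmHg. The model
explains why a vasoconstrictor that lowers both the CBF response and the
baseline venous oxygenation attenuates BOLD-CVR *less* than CBF-CVR: the
drop in Yv0 raises [dHb]0 and therefore BOLD signal leverage, partly
offsetting the smaller flow response (roughly a 30% flow-CVR reduction
against a ~15% BOLD-CVR reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class DavisParams:
    """Power-law parameters; defaults are conventional 3 T values."""

    alpha: float = 0.38
    beta: float = 1.5
    cbv0: float = 0.05  # baseline venous CBV fraction
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.cbv0 <= 0:
            raise ParameterError("cbv0 must be > 0")


@dataclass(frozen=True)
class HemodynamicState:
    """Baseline and hypercapnic physiology of one measurement state."""

    cbf0: float  # ml/100 g/min, room air
    cbf_hc: float  # ml/100 g/min, hypercapnia
    yv0: float  # baseline venous oxygenation fraction
    delta_etco2: float  # mmHg rise driving the response
    dhb0_override: float | None = None  # direct [dHb]0 in lieu of 1 - yv0

    def __post_init__(self) -> None:
        if self.cbf0 <= 0 or self.cbf_hc <= 0:
            raise ParameterError("CBF values must be > 0")
        if not 0 < self.yv0 < 1:
            raise ParameterError("yv0 must be in (0, 1)")
        if self.dhb0_override is not None and self.dhb0_override <= 0:
            raise ParameterError("dhb0 must be > 0")

    @property
    def dhb0(self) -> float:
        """Baseline deoxyhemoglobin content, proportional to 1 - Yv0."""
        if self.dhb0_override is not None:
            return self.dhb0_override
        return 1.0 - self.yv0

    @property
    def flow_ratio(self) -> float:
        return self.cbf_hc / self.cbf0

    def cbf_cvr(self) -> float:
        """Flow-based CVR implied by the state, %/mmHg."""
        if self.delta_etco2 <= 0:
            raise ParameterError("delta_etco2 must be > 0")
        return (self.flow_ratio - 1.0) * 100.0 / self.delta_etco2


def bold_response(state: HemodynamicState, p: DavisParams = DavisParams()) -> float:
    """Fractional BOLD change for the state's hypercapnic flow increase."""
    return (
        p.k
        * p.cbv0
        * state.dhb0**p.beta
        * (1.0 - state.flow_ratio ** (p.alpha - p.beta))
    )


def predicted_bold_cvr(
    state: HemodynamicState, p: DavisParams = DavisParams()
) -> float:
    """Model-predicted BOLD-CVR in %/mmHg."""
    if state.delta_etco2 <= 0:
        raise ParameterError("delta_etco2 must be > 0")
    return bold_response(state, p) * 100.0 / state.delta_etco2


@dataclass(frozen=True)
class AttenuationResult:
    """Percent reductions between two states (positive = reduction)."""

    cbf_cvr_change: float
    bold_cvr_change: float
    cbf_cvr_pre: float
    cbf_cvr_post: float
    bold_cvr_pre: float
    bold_cvr_post: float


def attenuation_analysis(
    pre: HemodynamicState,
    post: HemodynamicState,
    p: DavisParams = DavisParams(),
) -> AttenuationResult:
    """Compare flow-based and model-predicted BOLD CVR changes.

    Returns percent reductions ``(pre - post) / pre * 100`` of CBF-CVR and of
    the predicted BOLD-CVR. When the post state has both a weaker fractional
    flow response and a lower baseline venous oxygenation, the raised
    baseline deoxyhemoglobin partially offsets the flow deficit and the
    BOLD-CVR reduction is smaller than the CBF-CVR reduction.
    """
    cbf_pre, cbf_post = pre.cbf_cvr(), post.cbf_cvr()
    bold_pre, bold_post = predicted_bold_cvr(pre, p), predicted_bold_cvr(post, p)
    return AttenuationResult(
        cbf_cvr_change=(cbf_pre - cbf_post) / cbf_pre * 100.0,
        bold_cvr_change=(bold_pre - bold_post) / bold_pre * 100.0,
        cbf_cvr_pre=cbf_pre,
        cbf_cvr_post=cbf_post,
        bold_cvr_pre=bold_pre,
        bold_cvr_post=bold_post,
    )
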