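"""ORPO and DPO alignment objectives as pure functions of log-probabilities.

Both objectives compare a chosen completion y_w against a rejected
completion y_l for the same prompt x, acting only on sequence
log-probabilities — no model implementation is assumed, so the same code
scores a billion-parameter LLM and the toy character-level LM bundled
with this package.

ORPO (odds-ratio preference optimization) trains in a single stage:

    L_ORPO = L_SFT + beta * L_OR
    L_OR   = -log sigma( log [ odds(P(y_w|x)) / odds(P(y_l|x)) ] )

where odds(p) = p / (1-p) and L_SFT is the causal-LM negative
log-likelihood of the chosen completion. DPO instead compares a trainable
policy against a frozen reference model:

    L_DPO = -log sigma( beta * [ (log P(y_w) - log P_ref(y_w))
                               - (log P(y_l) - log P_ref(y_l)) ] )

All arithmetic is in nats and in log-space: log sigma(x) = -softplus(-x)
via log1p, so extreme log-probabilities (e.g. -1e4) stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CompletionLogProb",
    "OrpoLossParts",
    "DpoLossValue",
    "sequence_prob",
    "odds",
    "log_odds",
    "orpo_loss",
    "dpo_loss",
    "batch_loss",
    "DEFAULT_BETA_ORPO",
    "DEFAULT_BETA_DPO",
]

PROB_EPS = 1e-12
DEFAULT_BETA_ORPO = 0.25
DEFAULT_BETA_DPO = 0.1


@dataclass(frozen=True)
class CompletionLogProb:
    """Total log-probability (nats, <=0) of a completion and its token count."""

    total_logprob: float
    token_count: int = 1

    def __post_init__(self) -> None:
        if self.total_logprob > 0:
            raise ValueError(f"log-probability must be <=0, got {self.total_logprob}")
        if self.token_count < 1:
            raise ValueError(f"token_count must be >=1, got {self.token_count}")

    @property
    def per_token(self) -> float:
        return self.total_logprob / self.token_count


@dataclass(frozen=True)
class OrpoLossParts:
    sft_nll: float
    or_loss: float
    log_odds_ratio: float
    total: float


@dataclass(frozen=True)
class DpoLossValue:
    loss: float
    margin: float


def _softplus(x: float) -> float:
    # log(1 + e^x), stable for both tails
    if x > 0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


def sequence_prob(lp: CompletionLogProb, normalize: bool = True) -> float:
    """Completion probability in (0,1).

    With ``normalize`` the per-token geometric mean exp(logP / n) is
    returned; otherwise the joint exp(logP). Clamped to
    (eps, 1-eps), eps=1e-12, so odds are always finite.
    """
    z = lp.per_token if normalize else lp.total_logprob
    p = math.exp(z)
    return min(max(p, PROB_EPS), 1.0 - PROB_EPS)


def odds(p: float) -> float:
    """odds(p) = p / (1-p); strictly increasing on (0,1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0,1), got {p}")
    return p / (1.0 - p)


def _clamped_log(lp: CompletionLogProb, normalize: bool) -> float:
    z = lp.per_token if normalize else lp.total_logprob
    # guard only the p->1 side: the small-p tail is exact in log space
    return min(z, math.log1p(-PROB_EPS))


def log_odds(lp: CompletionLogProb, normalize: bool = True) -> float:
    """log[p/(1-p)] computed from the log-probability without forming p.

    Uses log(1-p) = log(-expm1(log p)) so probabilities as small as
    e^-10000 keep full precision (log-odds ~ log p there).
    """
    z = _clamped_log(lp, normalize)
    return z - math.log(-math.expm1(z))


def orpo_loss(
    chosen: CompletionLogProb,
    rejected: CompletionLogProb,
    beta: float = DEFAULT_BETA_ORPO,
    normalize: bool = True,
) -> OrpoLossParts:
    """Single-stage preference loss: SFT NLL plus beta times the odds-ratio term.

    ``normalize`` applies both to the probabilities entering the odds and
    to the SFT term (token-mean NLL vs token-sum). The default is
    length-normalized: joint probabilities of realistic completions are so
    small that odds(p) ~ p and beta loses its meaning across lengths.
    """
    if beta < 0:
        raise ValueError(f"beta must be >=0, got {beta}")
    lor = log_odds(chosen, normalize) - log_odds(rejected, normalize)
    or_loss = _softplus(-lor)  # -log sigma(log OR)
    sft_nll = -(chosen.per_token if normalize else chosen.total_logprob)
    return OrpoLossParts(
        sft_nll=sft_nll,
        or_loss=or_loss,
        log_odds_ratio=lor,
        total=sft_nll + beta * or_loss,
    )


def dpo_loss(
    policy_w: CompletionLogProb,
    policy_l: CompletionLogProb,
    ref_w: CompletionLogProb,
    ref_l: CompletionLogProb,
    beta: float = DEFAULT_BETA_DPO,
) -> DpoLossValue:
    """Reference-anchored preference loss on beta-scaled log-probability ratios."""
    if beta <= 0:
        raise ValueError(f"beta must be >0, got {beta}")
    margin = beta * (
        (policy_w.total_logprob - ref_w.total_logprob)
        - (policy_l.total_logprob - ref_l.total_logprob)
    )
    return DpoLossValue(loss=_softplus(-margin), margin=margin)


def batch_loss(
    records: Sequence[dict],
    beta: float,
    kind: Literal["orpo", "dpo"],
    normalize: bool = True,
) -> tuple[float, list]:
    """Mean loss over a batch plus per-record diagnostic parts.

    Each record holds ``chosen``/``rejected`` CompletionLogProbs and, for
    DPO, ``ref_chosen``/``ref_rejected``.
    """
    if not records:
        raise ValueError("batch must be non-empty")
    parts: list = []
    for rec in records:
        if kind == "orpo":
            parts.append(orpo_loss(rec["chosen"], rec["rejected"], beta, normalize))
        elif kind == "dpo":
            parts.append(dpo_loss(
                rec["chosen"], rec["rejected"], rec["ref_chosen"], rec["ref_rejected"], beta,
            ))
        else:
            raise ValueError(f"unknown loss kind: {kind!r}")
    totals = np.array([p.total if kind == "orpo" else p.loss for p in parts])
    return float(totals.mean()), parts
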