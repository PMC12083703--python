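"""Synthetic inputs for desk-scale testing of the full alignment pipeline.

Real preference alignment here would need an upstream multimodal
classifier (face+text or pathology vision-language model), gated clinical
databases and GPU fine-tuning of a billion-parameter LLM. This module
generates statistically controllable stand-ins for every stage instead:

* a label vocabulary and patient records with demographics and
  phenotype-term lists;
* an upstream classifier simulator whose top-1 accuracy is exactly
  calibrated to a target;
* an LLM-response simulator of controllable quality (with optional
  corruption to exercise hallucination detection);
* a small character-level causal language model, trained with the ORPO
  objective via analytic gradients, for end-to-end smoke tests;
* an AoR-sweep driver that runs build -> train -> respond -> evaluate per
  (k, q) grid point.

A single seeded :class:`numpy.random.Generator` is threaded through every
stochastic operation, so all outputs are replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import EvalConfig, evaluate, parse_ranked_list
from .label_space import (
    LabelEntry,
    LabelSpace,
    PatientRecord,
    TermDictionary,
    format_patient_prompt,
)
from .objectives import DEFAULT_BETA_ORPO, orpo_loss, CompletionLogProb
from .preference import (
    PreferenceRecord,
    RankedPrediction,
    aor_of,
    build_dataset,
    enforce_truth_first,
    rank_labels,
    render_numbered_list,
)

__all__ = [
    "SimulatorConfig",
    "ToyLmConfig",
    "make_label_space",
    "make_term_dictionary",
    "make_patients",
    "make_learnable_prompts",
    "simulate_upstream",
    "simulate_responses",
    "ToyCharLM",
    "train_toy_orpo",
    "respond_with_model",
    "sweep_aor",
]

logger = logging.getLogger(__name__)

# Study conditions: ~20-label vocabulary (tissue-task scale), a classifier
# at 80% top-1 accuracy, and 2,000 samples for calibration checks.
DEFAULT_N_LABELS = 20
DEFAULT_N_SAMPLES = 2000
DEFAULT_ACCURACY = 0.8


@dataclass
class SimulatorConfig:
    """Upstream-classifier simulator settings.

    ``accuracy`` is the target top-1 hit rate (probability that the truth
    ranks first); ``temperature`` scales the softmax over label logits.
    """

    n_labels: int = DEFAULT_N_LABELS
    n_samples: int = DEFAULT_N_SAMPLES
    accuracy: float = DEFAULT_ACCURACY
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0,1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_labels < 2 or self.n_samples < 1:
            raise ValueError("need >=2 labels and >=1 sample")


@dataclass
class ToyLmConfig:
    """Character-level causal LM hyperparameters (desk scale)."""

    context_len: int = 10
    embed_dim: int = 8
    hidden_dim: int = 48
    epochs: int = 15
    learning_rate: float = 0.01
    seed: int = 0


# --- vocabulary, patients, prompts ----------------------------------------

_SYLLABLES = [
    "bar", "cor", "del", "fen", "gal", "hel", "jor", "kel", "lun", "mar",
    "nor", "pel", "quin", "ros", "sel", "tor", "ulm", "vex", "wil", "xan",
    "yor", "zel", "bram", "crest", "dov", "fern",
]


def make_label_space(n_labels: int = DEFAULT_N_LABELS, seed: int = 0,
                     abbrev_fraction: float = 0.5) -> LabelSpace:
    """Generate a vocabulary of distinct pseudo-disease names.

    A fraction of entries carry an upper-case abbreviation, mirroring the
    "Full Name (ABBR)" convention of clinical disease naming.
    """
    rng = np.random.default_rng(seed)
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n_labels:
        parts = rng.choice(_SYLLABLES, size=2, replace=False)
        base = "".join(parts)
        name = f"{base.capitalize()} syndrome"
        if name.casefold() in seen:
            name = f"{base.capitalize()} syndrome, type {len(names)}"
        seen.add(name.casefold())
        names.append(name)
    entries = []
    for i, name in enumerate(names):
        abbrev = None
        if rng.random() < abbrev_fraction:
            word = name.split(" ")[0]
            abbrev = (word[:3] + "S" + str(i)).upper()
        entries.append(LabelEntry(name, abbrev, i))
    return LabelSpace(entries)


def make_term_dictionary(n_terms: int = 40, seed: int = 0) -> TermDictionary:
    """Generate an HPO-style dictionary of phenotype term texts."""
    rng = np.random.default_rng(seed)
    adjectives = ["Mild", "Severe", "Progressive", "Congenital", "Recurrent", "Global"]
    features = [
        "developmental delay", "muscular hypotonia", "seizure", "short stature",
        "strabismus", "scoliosis", "hearing impairment", "intellectual disability",
        "cardiac anomaly", "macrocephaly", "microcephaly", "joint laxity",
    ]
    mapping: dict[str, str] = {}
    i = 0
    while len(mapping) < n_terms:
        text = f"{rng.choice(adjectives)} {rng.choice(features)}"
        tid = f"HP:{7000000 + i:07d}"
        if text not in mapping.values():
            mapping[tid] = text
        i += 1
    return TermDictionary(mapping)


def make_patients(n: int, space: LabelSpace, dictionary: TermDictionary,
                  seed: int = 0) -> list[PatientRecord]:
    """Random patient records: demographics plus 2-5 phenotype term ids."""
    rng = np.random.default_rng(seed)
    term_ids = sorted(dictionary.mapping)
    sexes = ["male", "female"]
    ethnicities = ["Caucasian", "East Asian", "South Asian", "African", "Hispanic"]
    labels = space.names()
    out = []
    for i in range(n):
        n_terms = int(rng.integers(2, 6))
        ids = list(rng.choice(term_ids, size=n_terms, replace=False))
        out.append(PatientRecord(
            sample_id=f"S{i:05d}",
            age=f"{int(rng.integers(1, 18))}-year-old",
            sex=str(rng.choice(sexes)),
            ethnicity=str(rng.choice(ethnicities)),
            phenotype_term_ids=ids,
            true_label=str(labels[int(rng.integers(len(labels)))]),
        ))
    return out


def make_learnable_prompts(truths: dict[str, str], space: LabelSpace,
                           seed: int = 0) -> dict[str, str]:
    """Prompts whose text determines the true label (separable task).

    Each label is assigned a distinct pseudo-word feature code; prompts
    mention only the code, so a model must learn the code-to-label mapping.
    Used by the toy-LM smoke tests, where learnability matters more than
    clinical realism.
    """
    rng = np.random.default_rng(seed)
    codes: dict[str, str] = {}
    for e in space.entries:
        parts = rng.choice(_SYLLABLES, size=2, replace=False)
        code = "".join(parts)
        while code in codes.values():
            code = "".join(rng.choice(_SYLLABLES, size=2, replace=False))
        codes[e.canonical_name] = code
    return {
        sid: f"Observed marker: {codes[label]}."
        for sid, label in truths.items()
    }


# --- upstream classifier simulator ----------------------------------------

def simulate_upstream(cfg: SimulatorConfig, space: LabelSpace,
                      truths: Sequence[str],
                      sample_ids: Optional[Sequence[str]] = None) -> list[RankedPrediction]:
    """Simulate ranked softmax predictions with calibrated top-1 accuracy.

    Per sample, label logits are drawn i.i.d. standard normal and passed
    through a softmax at ``cfg.temperature``. A seeded Bernoulli(accuracy)
    draw then decides whether the truth's logit is swapped with the
    current maximum (truth ranks first) or, if the truth already leads,
    swapped away (truth does not rank first) — so the top-1 hit rate is
    exactly Bernoulli-calibrated to ``accuracy``.
    """
    rng = np.random.default_rng(cfg.seed)
    names = space.names()
    idx = {n: i for i, n in enumerate(names)}
    if sample_ids is None:
        sample_ids = [f"S{s:05d}" for s in range(len(truths))]
    elif len(sample_ids) != len(truths):
        raise ValueError("sample_ids and truths must have equal length")
    preds: list[RankedPrediction] = []
    for s, truth in enumerate(truths):
        logits = rng.standard_normal(len(names))
        t = idx[truth]
        j = int(np.argmax(logits))
        if rng.random() < cfg.accuracy:
            if j != t:
                logits[t], logits[j] = logits[j], logits[t]
        else:
            if j == t:
                others = [i for i in range(len(names)) if i != t]
                swap = int(rng.choice(others))
                logits[t], logits[swap] = logits[swap], logits[t]
        z = logits / cfg.temperature
        z -= z.max()
        probs = np.exp(z)
        probs /= probs.sum()
        preds.append(RankedPrediction(
            sample_id=str(sample_ids[s]),
            scores={n: float(p) for n, p in zip(names, probs)},
            true_label=truth,
        ))
    return preds


def _gibberish(rng: np.random.Generator, length: int = 12) -> str:
    return "".join(chr(int(c)) for c in rng.integers(ord("a"), ord("z") + 1, length))


def simulate_responses(
    preds: Sequence[RankedPrediction],
    space: LabelSpace,
    quality: float,
    n_top: int,
    seed: int = 0,
    corruption_rate: float = 0.0,
) -> list[dict]:
    """Simulate LLM responses of controllable quality.

    With probability ``quality`` a response is the truth-first top-``n_top``
    list of the upstream prediction rendered as a numbered block; otherwise
    it is a uniformly random label list. Independently, with probability
    ``corruption_rate`` one entry is replaced by a fabricated name, which
    should fail the hallucination check.
    """
    if not 0.0 <= quality <= 1.0 or not 0.0 <= corruption_rate <= 1.0:
        raise ValueError("quality and corruption_rate must lie in [0,1]")
    rng = np.random.default_rng(seed)
    names = space.names()
    out = []
    for pred in preds:
        if rng.random() < quality:
            ranked = rank_labels(pred, space)
            listed = enforce_truth_first(ranked, pred.true_label, n_top)
            from_truth = True
        else:
            listed = list(rng.choice(names, size=n_top, replace=False))
            from_truth = False
        corrupted = rng.random() < corruption_rate
        if corrupted:
            pos = int(rng.integers(len(listed)))
            listed = list(listed)
            listed[pos] = _gibberish(rng)
        out.append({
            "id": pred.sample_id,
            "text": render_numbered_list(listed),
            "from_truth": from_truth,
            "corrupted": corrupted,
        })
    return out


# --- toy character-level causal LM ----------------------------------------

PAD = "\x00"


class ToyCharLM:
    """A tiny fixed-window character-level causal language model.

    Architecture: character embeddings, the last ``context_len`` embeddings
    concatenated, one tanh hidden layer, softmax over the character
    vocabulary. Small enough to overfit a ~20-label code-to-name mapping
    in well under a minute on one CPU, which is all the end-to-end ORPO
    smoke tests require.
    """

    def __init__(self, texts: Iterable[str], cfg: ToyLmConfig):
        charset = sorted(set("".join(texts)) | {PAD})
        self.chars = charset
        self.stoi = {c: i for i, c in enumerate(charset)}
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        V, d, h, C = len(charset), cfg.embed_dim, cfg.hidden_dim, cfg.context_len
        scale = 0.1
        self.E = rng.standard_normal((V, d)) * scale
        self.W1 = rng.standard_normal((C * d, h)) * scale
        self.b1 = np.zeros(h)
        self.W2 = rng.standard_normal((h, V)) * scale
        self.b2 = np.zeros(V)
        self._adam_state: Optional[list] = None
        self._adam_t = 0

    # - forward -

    def _encode(self, text: str) -> np.ndarray:
        default = self.stoi[PAD]
        return np.array([self.stoi.get(c, default) for c in text], dtype=np.int64)

    def _contexts(self, prompt: str, completion: str) -> tuple[np.ndarray, np.ndarray]:
        """(n_completion, context_len) context index matrix and target indices."""
        C = self.cfg.context_len
        seq = self._encode(PAD * C + prompt + completion)
        start = C + len(prompt)
        ctx = np.stack([seq[i - C:i] for i in range(start, start + len(completion))])
        tgt = seq[start:start + len(completion)]
        return ctx, tgt

    def _forward(self, ctx: np.ndarray):
        x = self.E[ctx].reshape(ctx.shape[0], -1)       # (n, C*d)
        pre = x @ self.W1 + self.b1
        hid = np.tanh(pre)
        logits = hid @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return x, hid, probs

    def completion_logprob(self, prompt: str, completion: str) -> CompletionLogProb:
        """Total log-probability of the completion characters given the prompt."""
        if not completion:
            raise ValueError("completion must be non-empty")
        ctx, tgt = self._contexts(prompt, completion)
        _, _, probs = self._forward(ctx)
        lp = float(np.log(probs[np.arange(len(tgt)), tgt] + 1e-300).sum())
        return CompletionLogProb(min(lp, 0.0), token_count=len(tgt))

    def score_labels(self, prompt: str, names: Sequence[str],
                     render: bool = True) -> list[str]:
        """Rank label names by length-normalized completion log-probability."""
        scored = []
        for i, name in enumerate(names):
            completion = render_numbered_list([name]) if render else name
            lp = self.completion_logprob(prompt, completion)
            scored.append((-lp.per_token, i, name))
        scored.sort()
        return [name for _, _, name in scored]

    # - ORPO training -

    def _grad_record(self, prompt: str, chosen: str, rejected: str, beta: float):
        """Analytic ORPO gradient for one preference record.

        With z = (sum of token log-probs)/n and g(z) = z - log(1-e^z) the
        per-record loss is  L = -z_w + beta * softplus(g(z_l) - g(z_w));
        dL/dz_w = -1 - beta*s/(1-e^{z_w}),  dL/dz_l = beta*s/(1-e^{z_l})
        with s = sigma(g(z_l) - g(z_w)). The z-gradients chain through the
        usual softmax cross-entropy Jacobian at every completion position.
        """
        grads = {k: np.zeros_like(v) for k, v in self._params().items()}
        sides = {}
        for side, completion in (("w", chosen), ("l", rejected)):
            ctx, tgt = self._contexts(prompt, completion)
            x, hid, probs = self._forward(ctx)
            lp = np.log(probs[np.arange(len(tgt)), tgt] + 1e-300)
            sides[side] = (ctx, tgt, x, hid, probs, float(lp.sum()), len(tgt))
        z_w = sides["w"][5] / sides["w"][6]
        z_l = sides["l"][5] / sides["l"][6]
        z_w, z_l = min(z_w, -1e-12), min(z_l, -1e-12)
        d_margin = (z_w - np.log(-np.expm1(z_w))) - (z_l - np.log(-np.expm1(z_l)))
        s = 1.0 / (1.0 + np.exp(d_margin))       # sigma(-margin)
        dz = {
            "w": -1.0 - beta * s / -np.expm1(z_w),
            "l": beta * s / -np.expm1(z_l),
        }
        for side in ("w", "l"):
            ctx, tgt, x, hid, probs, _, n = sides[side]
            # dL/dlogits = dL/dz * (1/n) * (onehot - softmax) = -dz/n * (softmax - onehot)
            dlogits = probs.copy()
            dlogits[np.arange(len(tgt)), tgt] -= 1.0
            dlogits *= -dz[side] / n
            grads["W2"] += hid.T @ dlogits
            grads["b2"] += dlogits.sum(axis=0)
            dhid = dlogits @ self.W2.T * (1.0 - hid ** 2)
            grads["W1"] += x.T @ dhid
            grads["b1"] += dhid.sum(axis=0)
            dx = (dhid @ self.W1.T).reshape(ctx.shape[0], ctx.shape[1], -1)
            np.add.at(grads["E"], ctx, dx)
        loss = orpo_loss(
            CompletionLogProb(min(sides["w"][5], 0.0), sides["w"][6]),
            CompletionLogProb(min(sides["l"][5], 0.0), sides["l"][6]),
            beta=beta,
        )
        return grads, loss

    def _params(self) -> dict[str, np.ndarray]:
        return {"E": self.E, "W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        params = self._params()
        if self._adam_state is None:
            self._adam_state = [
                {k: np.zeros_like(v) for k, v in params.items()},
                {k: np.zeros_like(v) for k, v in params.items()},
            ]
        m, v = self._adam_state
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, p in params.items():
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1 ** t)
            vhat = v[k] / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _mean_margin(model: ToyCharLM, prefs: Sequence[PreferenceRecord],
                 beta: float) -> tuple[float, float, float]:
    """(mean log-odds-ratio margin, mean sft_nll, mean or_loss) over records."""
    margins, sfts, ors = [], [], []
    for rec in prefs:
        parts = orpo_loss(
            model.completion_logprob(rec.prompt, rec.chosen_text),
            model.completion_logprob(rec.prompt, rec.rejected_text),
            beta=beta,
        )
        margins.append(parts.log_odds_ratio)
        sfts.append(parts.sft_nll)
        ors.append(parts.or_loss)
    return float(np.mean(margins)), float(np.mean(sfts)), float(np.mean(ors))


def train_toy_orpo(
    prefs: Sequence[PreferenceRecord],
    cfg: ToyLmConfig,
    beta: float = DEFAULT_BETA_ORPO,
) -> tuple[ToyCharLM, pd.DataFrame]:
    """Train the toy LM with the ORPO objective; return model and epoch log.

    The log records, per epoch (epoch 0 = before any update), the mean
    chosen-vs-rejected log-odds-ratio margin, mean SFT NLL and mean
    odds-ratio loss over the training records. A non-finite loss aborts
    with the offending record identified.
    """
    if not prefs:
        raise ValueError("preference records must be non-empty")
    texts = [rec.prompt + rec.chosen_text + rec.rejected_text for rec in prefs]
    model = ToyCharLM(texts, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    margin, sft, orl = _mean_margin(model, prefs, beta)
    rows.append({"epoch": 0, "mean_log_odds_ratio": margin,
                 "mean_sft_nll": sft, "mean_or_loss": orl})
    order = np.arange(len(prefs))
    for epoch in range(1, cfg.epochs + 1):
        rng.shuffle(order)
        for i in order:
            rec = prefs[int(i)]
            grads, loss = model._grad_record(
                rec.prompt, rec.chosen_text, rec.rejected_text, beta)
            if not np.isfinite(loss.total):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"sample {rec.sample_id}"
                )
            model._adam_step(grads, cfg.learning_rate)
        margin, sft, orl = _mean_margin(model, prefs, beta)
        rows.append({"epoch": epoch, "mean_log_odds_ratio": margin,
                     "mean_sft_nll": sft, "mean_or_loss": orl})
    return model, pd.DataFrame(rows)


def respond_with_model(
    model: ToyCharLM,
    prompts: dict[str, str],
    space: LabelSpace,
    n_top: int,
) -> list[dict]:
    """Deterministic responses: rank all labels by model score, list top n."""
    names = space.names()
    out = []
    for sid in prompts:
        ranked = model.score_labels(prompts[sid], names)
        out.append({"id": sid, "text": render_numbered_list(ranked[:n_top])})
    return out


# --- AoR sweep -------------------------------------------------------------

def sweep_aor(
    k_q_grid: Sequence[tuple[int, int]],
    space: LabelSpace,
    preds: Sequence[RankedPrediction],
    prompts: dict[str, str],
    truths: dict[str, str],
    n_top: int = 5,
    lambda_weight: float = 1.0,
    responder: Literal["simulated", "toy"] = "simulated",
    quality: float = 0.9,
    toy_cfg: Optional[ToyLmConfig] = None,
    beta: float = DEFAULT_BETA_ORPO,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the pipeline per (k, q) grid point and tabulate the metrics.

    Each feasible grid point builds a preference dataset, obtains
    responses (from the quality-controlled simulator, or from a toy LM
    trained on that dataset), and evaluates them. Infeasible points
    (k+q exceeding the label count) are skipped with a warning.
    """
    rows = []
    for k, q in k_q_grid:
        if k + q > len(space):
            logger.warning("skipping infeasible grid point (k=%d, q=%d)", k, q)
            continue
        records = build_dataset(preds, prompts, space, k, q)
        if responder == "toy":
            model, _ = train_toy_orpo(records, toy_cfg or ToyLmConfig(seed=seed), beta)
            raw = respond_with_model(model, prompts, space, n_top)
        else:
            raw = simulate_responses(preds, space, quality, n_top, seed=seed)
        responses = [parse_ranked_list(r["text"], n_top, r["id"]) for r in raw]
        cfg = EvalConfig(n_top=n_top, k=k, q=q, lambda_weight=lambda_weight)
        report = evaluate(responses, truths, {p.sample_id: p for p in preds}, space, cfg)
        rows.append({
            "k": k, "q": q, "aor": aor_of(k, q),
            "hfa_rate": report.hfa_rate, "topn_rate": report.topn_rate,
            "top1_rate": report.top1_rate, "car": report.car,
        })
    return pd.DataFrame(rows)
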