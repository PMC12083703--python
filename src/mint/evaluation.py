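"""Automated grading of ranked-list LLM responses (LLM-Eval).

Responses are free text expected to carry a numbered ranked list of label
names. Grading proceeds in a logical chain:

* **HFA** (hallucination-free accuracy): does every parsed name plausibly
  belong to the label vocabulary? Similarity threshold 0.6 — lenient, the
  point is to catch fabricated names and ignored instructions.
* **Top-N / Top-1**: only for HFA-passing responses, does the truth appear
  among the first N names / as the first name? Threshold 0.8 — strict.
* **CAR** (coverage-avoidance rate): the weighted harmonic mean of the
  top-k coverage rate C (fraction of the response drawn from the upstream
  classifier's top-k, truth first) and the bottom-q avoidance rate A
  (fraction avoiding the upstream bottom-q):

      CAR(k,q,lambda) = (1/N) sum_i (1+lambda) C_i A_i / (lambda C_i + A_i)

Name comparison uses the Ratcliff/Obershelp ratio (difflib's
SequenceMatcher) on normalized strings, with a parenthesized-abbreviation
path so "Cornelia de Lange Syndrome (CdLS)" matches either the full name
or the abbreviation "CdLS".
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Literal, Mapping, Optional, Sequence

from .label_space import LabelEntry, LabelSpace, normalize
from .preference import RankedPrediction, enforce_truth_first, rank_labels

__all__ = [
    "ParsedResponse",
    "EvalConfig",
    "SampleDiagnostics",
    "EvalReport",
    "parse_ranked_list",
    "similarity",
    "match_label",
    "match_any_label",
    "hfa",
    "topn_hit",
    "top1_hit",
    "coverage_rate",
    "avoidance_rate",
    "car",
    "evaluate",
    "read_responses_jsonl",
]

HFA_THRESHOLD = 0.6
MATCH_THRESHOLD = 0.8


@dataclass
class ParsedResponse:
    """The ordered list R_i of names extracted from one response."""

    sample_id: str
    names: list[str]
    parse_ok: bool
    truncated: bool = False


@dataclass
class EvalConfig:
    """Knobs of the grading chain; thresholds default to 0.6 (HFA) / 0.8 (strict)."""

    n_top: int = 10
    k: int = 10
    q: int = 10
    lambda_weight: float = 1.0
    hfa_threshold: float = HFA_THRESHOLD
    match_threshold: float = MATCH_THRESHOLD
    hfa_rule: Literal["all", "any", "majority"] = "all"
    raw_similarity: bool = False  # skip normalization before the ratio

    def __post_init__(self) -> None:
        if not (0.0 <= self.hfa_threshold <= 1.0 and 0.0 <= self.match_threshold <= 1.0):
            raise ValueError("similarity thresholds must lie in [0,1]")
        if self.hfa_threshold > self.match_threshold:
            raise ValueError("hfa_threshold must not exceed match_threshold")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >=0")


@dataclass
class SampleDiagnostics:
    sample_id: str
    parse_ok: bool
    hfa_pass: bool
    topn_pass: bool
    top1_pass: bool
    coverage: float
    avoidance: float
    empty_response: bool = False


@dataclass
class EvalReport:
    """Aggregate rates (percent) plus per-sample diagnostics.

    By construction top1_rate <= topn_rate <= hfa_rate: Top-N and Top-1
    are graded only on HFA-passing samples and count as failures elsewhere.
    """

    hfa_rate: float
    topn_rate: float
    top1_rate: float
    car: float
    per_sample: list[SampleDiagnostics] = field(default_factory=list)
    config: Optional[EvalConfig] = None

    def to_dict(self) -> dict:
        out = {
            "hfa_rate": self.hfa_rate,
            "topn_rate": self.topn_rate,
            "top1_rate": self.top1_rate,
            "car": self.car,
            "n_samples": len(self.per_sample),
        }
        if self.config is not None:
            out["config"] = {
                "n_top": self.config.n_top, "k": self.config.k, "q": self.config.q,
                "lambda_weight": self.config.lambda_weight,
                "hfa_threshold": self.config.hfa_threshold,
                "match_threshold": self.config.match_threshold,
                "hfa_rule": self.config.hfa_rule,
            }
        return out


# --- parsing ---------------------------------------------------------------

_ITEM = re.compile(r"^\s*(?:\d+\s*[.)\]:]|[-*•])\s*(.+?)\s*$")


def parse_ranked_list(text: str, expected_len: Optional[int] = None,
                      sample_id: str = "") -> ParsedResponse:
    """Extract the ranked name list from free text; never raises.

    Accepts "1. name", "2) name", "3] name", "4: name" and bulleted
    ("- name", "* name") items; numbering and surrounding whitespace are
    stripped, order preserved. Zero extracted items yields
    ``parse_ok=False``; items beyond ``expected_len`` are truncated and
    flagged.
    """
    names: list[str] = []
    for line in (text or "").splitlines():
        m = _ITEM.match(line)
        if m and m.group(1).strip():
            names.append(m.group(1).strip())
    truncated = False
    if expected_len is not None and len(names) > expected_len:
        names = names[:expected_len]
        truncated = True
    return ParsedResponse(sample_id, names, parse_ok=bool(names), truncated=truncated)


# --- fuzzy matching --------------------------------------------------------

def similarity(a: str, b: str, raw: bool = False) -> float:
    """Ratcliff/Obershelp ratio 2M/T on normalized strings, in [0,1]."""
    if not raw:
        a, b = normalize(a), normalize(b)
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return SequenceMatcher(None, a, b, autojunk=False).ratio()


_PARENS = re.compile(r"\(([^()]*)\)")


def _candidate_forms(candidate: str) -> list[str]:
    """The candidate itself, any parenthesized token, and the de-parenthesized rest."""
    forms = [candidate]
    inner = _PARENS.findall(candidate)
    forms.extend(tok.strip() for tok in inner if tok.strip())
    stripped = _PARENS.sub(" ", candidate).strip()
    if stripped and stripped != candidate:
        forms.append(stripped)
    return forms


def _entry_forms(entry: LabelEntry) -> list[str]:
    forms = [entry.canonical_name]
    if entry.abbreviation:
        forms.append(entry.abbreviation)
    return forms


def match_label(candidate: str, entry: LabelEntry, threshold: float = MATCH_THRESHOLD,
                raw: bool = False) -> bool:
    """Does a response name match a vocabulary entry at the given threshold?

    Every candidate form (full string, parenthesized abbreviation,
    abbreviation-stripped remainder) is compared against every entry form
    (canonical name, abbreviation); the best ratio decides.
    """
    return best_similarity(candidate, entry, raw) >= threshold


def best_similarity(candidate: str, entry: LabelEntry, raw: bool = False) -> float:
    return max(
        similarity(cf, ef, raw)
        for cf in _candidate_forms(candidate)
        for ef in _entry_forms(entry)
    )


def match_any_label(candidate: str, space: LabelSpace, threshold: float,
                    raw: bool = False) -> bool:
    """Is the candidate plausibly any vocabulary entry? (HFA inner check)"""
    hit = space.lookup_any(candidate)  # exact normalized hit short-circuits
    if hit is not None:
        return True
    return any(match_label(candidate, e, threshold, raw) for e in space.entries)


# --- metric chain ----------------------------------------------------------

def _hfa_pass(resp: ParsedResponse, space: LabelSpace, cfg: EvalConfig) -> bool:
    if not resp.parse_ok:
        return False
    flags = [match_any_label(n, space, cfg.hfa_threshold, cfg.raw_similarity)
             for n in resp.names]
    if cfg.hfa_rule == "all":
        return all(flags)
    if cfg.hfa_rule == "any":
        return any(flags)
    return sum(flags) * 2 > len(flags)  # majority


def hfa(responses: Sequence[ParsedResponse], space: LabelSpace,
        cfg: EvalConfig) -> tuple[float, list[bool]]:
    """Hallucination-free accuracy in percent, plus per-sample pass flags."""
    if not responses:
        raise ValueError("empty response set")
    flags = [_hfa_pass(r, space, cfg) for r in responses]
    return 100.0 * sum(flags) / len(flags), flags


def topn_hit(resp: ParsedResponse, truth: LabelEntry, cfg: EvalConfig) -> bool:
    """Truth among the first n_top names at the strict threshold?"""
    return any(
        match_label(name, truth, cfg.match_threshold, cfg.raw_similarity)
        for name in resp.names[: cfg.n_top]
    )


def top1_hit(resp: ParsedResponse, truth: LabelEntry, cfg: EvalConfig) -> bool:
    """Truth as the first name at the strict threshold?"""
    if not resp.names:
        return False
    return match_label(resp.names[0], truth, cfg.match_threshold, cfg.raw_similarity)


def _greedy_match_count(names: Sequence[str], pool: Sequence[str],
                        threshold: float, raw: bool) -> int:
    """Greedy best-similarity one-to-one assignment between names and pool.

    Each response name and each pool member is usable at most once. At
    threshold 1.0 (with normalization) this reduces to multiset
    intersection, which the exact-matching oracle tests exploit.
    """
    pairs = []
    for i, n in enumerate(names):
        for j, p in enumerate(pool):
            s = similarity(n, p, raw)
            if s >= threshold:
                pairs.append((-s, i, j))
    pairs.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    count = 0
    for _, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        count += 1
    return count


def coverage_rate(resp: ParsedResponse, top_k: Sequence[str], cfg: EvalConfig) -> float:
    """C = |matches between R_i and the truth-first top-k| / |R_i|."""
    if not resp.names:
        return 0.0
    m = _greedy_match_count(resp.names, top_k, cfg.match_threshold, cfg.raw_similarity)
    return m / len(resp.names)


def avoidance_rate(resp: ParsedResponse, bottom_q: Sequence[str], cfg: EvalConfig) -> float:
    """A = 1 - |matches between R_i and the bottom-q| / |R_i|."""
    if not resp.names:
        return 0.0
    m = _greedy_match_count(resp.names, bottom_q, cfg.match_threshold, cfg.raw_similarity)
    return 1.0 - m / len(resp.names)


def car(per_sample: Sequence[tuple[float, float]], lambda_weight: float = 1.0) -> float:
    """Mean weighted harmonic mean of (coverage, avoidance) pairs.

    Per-sample term (1+lambda) C A / (lambda C + A), defined as 0 when the
    denominator vanishes. lambda=1 is the plain harmonic mean; lambda->0
    recovers C, lambda->infinity recovers A.
    """
    if not per_sample:
        raise ValueError("empty per-sample list")
    if lambda_weight < 0:
        raise ValueError("lambda must be >=0")
    total = 0.0
    for c, a in per_sample:
        if not (0.0 <= c <= 1.0 and 0.0 <= a <= 1.0):
            raise ValueError(f"coverage/avoidance outside [0,1]: ({c}, {a})")
        denom = lambda_weight * c + a
        total += (1.0 + lambda_weight) * c * a / denom if denom > 0 else 0.0
    return total / len(per_sample)


def evaluate(
    responses: Sequence[ParsedResponse],
    truths: Mapping[str, str],
    upstream_preds: Mapping[str, RankedPrediction],
    space: LabelSpace,
    cfg: EvalConfig,
) -> EvalReport:
    """Run the full grading chain over aligned responses/truths/predictions.

    Sample ids must align across all three inputs. Top-N and Top-1 are
    graded only for HFA-passing samples and counted as failures otherwise,
    so top1_rate <= topn_rate <= hfa_rate holds on every run. The coverage
    list T_k has the truth swapped into first position, mirroring the
    chosen-list construction.
    """
    if not responses:
        raise ValueError("empty response set")
    resp_ids = [r.sample_id for r in responses]
    missing_t = [i for i in resp_ids if i not in truths]
    missing_p = [i for i in resp_ids if i not in upstream_preds]
    if missing_t or missing_p:
        raise KeyError(
            f"sample ids without ground truth: {missing_t[:5]}; "
            f"without upstream prediction: {missing_p[:5]}"
        )
    diags: list[SampleDiagnostics] = []
    ca_pairs: list[tuple[float, float]] = []
    for resp in responses:
        truth_entry = space.lookup(truths[resp.sample_id])
        pred = upstream_preds[resp.sample_id]
        ranked = rank_labels(pred, space)
        top_k = enforce_truth_first(ranked, pred.true_label, cfg.k)
        bottom_q = list(reversed(ranked[-cfg.q:]))
        hfa_ok = _hfa_pass(resp, space, cfg)
        tn = hfa_ok and topn_hit(resp, truth_entry, cfg)
        t1 = hfa_ok and top1_hit(resp, truth_entry, cfg)
        c = coverage_rate(resp, top_k, cfg)
        a = avoidance_rate(resp, bottom_q, cfg)
        ca_pairs.append((c, a))
        diags.append(SampleDiagnostics(
            sample_id=resp.sample_id, parse_ok=resp.parse_ok, hfa_pass=hfa_ok,
            topn_pass=tn, top1_pass=t1, coverage=c, avoidance=a,
            empty_response=not resp.names,
        ))
    n = len(diags)
    report = EvalReport(
        hfa_rate=100.0 * sum(d.hfa_pass for d in diags) / n,
        topn_rate=100.0 * sum(d.topn_pass for d in diags) / n,
        top1_rate=100.0 * sum(d.top1_pass for d in diags) / n,
        car=car(ca_pairs, cfg.lambda_weight),
        per_sample=diags,
        config=cfg,
    )
    assert report.top1_rate <= report.topn_rate <= report.hfa_rate
    return report


def read_responses_jsonl(path, expected_len: Optional[int] = None) -> list[ParsedResponse]:
    """Read ``{id, text}`` objects and parse each into a ranked list."""
    out: list[ParsedResponse] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "_meta" in obj:
                continue
            out.append(parse_ranked_list(obj["text"], expected_len, obj["id"]))
    return out
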