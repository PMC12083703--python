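"""Preference-learning dataset construction from ranked classifier output.

An upstream multimodal classifier (e.g. a face+text Transformer for rare
diseases, or a pathology vision-language model for tissue types) scores
every label in the vocabulary. The top-k labels become the "chosen" list
of a preference pair — with the ground truth forced into first position —
and the bottom-q labels become the "rejected" list. The ratio k/q is the
acceptance-over-rejection (AoR) ratio of the resulting dataset.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .label_space import LabelSpace

__all__ = [
    "RankedPrediction",
    "PreferenceRecord",
    "SftRecord",
    "rank_labels",
    "enforce_truth_first",
    "build_preference_record",
    "build_sft_record",
    "aor_of",
    "build_dataset",
    "render_numbered_list",
    "read_rankings_jsonl",
    "write_preferences_jsonl",
]

logger = logging.getLogger(__name__)

# Sum-to-one tolerance for probability vectors: accept silently within
# STRICT_TOL, renormalize with a warning within RENORM_TOL, reject beyond.
STRICT_TOL = 1e-6
RENORM_TOL = 1e-3


@dataclass
class RankedPrediction:
    """One sample's upstream-classifier output.

    ``scores`` maps canonical label names to probabilities; they must sum
    to one (within tolerance) and every name, including the truth, must
    belong to the label space.
    """

    sample_id: str
    scores: dict[str, float]
    true_label: str

    def validate(self, space: LabelSpace, k: int = 1, q: int = 1) -> "RankedPrediction":
        for name in self.scores:
            if name not in space:
                raise ValueError(f"scored label not in space: {name!r} (sample {self.sample_id})")
        if self.true_label not in space:
            raise ValueError(f"true label not in space: {self.true_label!r}")
        if len(self.scores) < k + q:
            raise ValueError(
                f"sample {self.sample_id}: {len(self.scores)} scored labels cannot "
                f"support k+q={k + q} (AoR={k}/{q} infeasible)"
            )
        total = math.fsum(self.scores.values())
        if abs(total - 1.0) > RENORM_TOL:
            raise ValueError(
                f"sample {self.sample_id}: probabilities sum to {total:.6g}, not 1"
            )
        if abs(total - 1.0) > STRICT_TOL:
            logger.warning(
                "sample %s: probabilities sum to %.8f; renormalizing", self.sample_id, total
            )
            self.scores = {n: p / total for n, p in self.scores.items()}
        return self


@dataclass
class PreferenceRecord:
    """One training example: prompt, chosen top-k (truth first), rejected bottom-q."""

    sample_id: str
    prompt: str
    chosen: list[str]
    rejected: list[str]

    @property
    def chosen_text(self) -> str:
        return render_numbered_list(self.chosen)

    @property
    def rejected_text(self) -> str:
        return render_numbered_list(self.rejected)


@dataclass
class SftRecord:
    """Supervised fine-tuning example: prompt and a target naming the truth."""

    sample_id: str
    prompt: str
    target: str


def render_numbered_list(names: Sequence[str]) -> str:
    """Render names as the structured numbered block used for model output."""
    return "\n".join(f"{i + 1}. {name}" for i, name in enumerate(names))


def rank_labels(pred: RankedPrediction, space: LabelSpace) -> list[str]:
    """All scored labels, most probable first.

    Ties are broken by ascending ``label_id`` so the ranking is canonical:
    permuting the iteration order of the scores map never changes it.
    """
    return sorted(
        pred.scores,
        key=lambda name: (-pred.scores[name], space.label_id_of(name)),
    )


def enforce_truth_first(ranked: Sequence[str], truth: str, k: int) -> list[str]:
    """Top-k slice of ``ranked`` with the ground truth forced to position 0.

    If the truth already leads, the slice is returned unchanged; if it sits
    elsewhere inside the top-k it is swapped with position 0 (preserving
    the label set); if it falls outside the top-k it is inserted at the
    front and the former k-th label dropped. All other relative order is
    preserved.
    """
    if k < 1:
        raise ValueError(f"k must be >=1, got {k}")
    if len(ranked) < k:
        raise ValueError(f"ranked list of {len(ranked)} cannot supply top-{k}")
    top = list(ranked[:k])
    norm_truth = truth
    if norm_truth in top:
        i = top.index(norm_truth)
        if i != 0:
            top[0], top[i] = top[i], top[0]
        return top
    return [truth] + top[: k - 1]


def build_preference_record(
    pred: RankedPrediction,
    prompt: str,
    space: LabelSpace,
    k: int,
    q: int,
) -> PreferenceRecord:
    """Build one chosen/rejected pair from a ranked prediction.

    chosen = truth-first top-k; rejected = bottom-q ordered least-probable
    first. If the truth lands in the bottom-q it is removed from the
    rejected list (it now leads the chosen list) and the next-lowest
    unused label is backfilled, so chosen and rejected are always disjoint.
    """
    if k < 1 or q < 1:
        raise ValueError("k and q must both be >=1")
    pred.validate(space, k=k, q=q)
    ranked = rank_labels(pred, space)
    if k + q > len(ranked):
        raise ValueError(
            f"k+q={k + q} exceeds the {len(ranked)} scored labels: AoR={k}/{q} infeasible"
        )
    chosen = enforce_truth_first(ranked, pred.true_label, k)
    rejected = list(reversed(ranked[-q:]))  # least probable first
    if pred.true_label in rejected:
        rejected.remove(pred.true_label)
        used = set(chosen) | set(rejected)
        for cand in reversed(ranked):  # next-lowest unused label
            if cand not in used:
                rejected.append(cand)
                break
    overlap = set(chosen) & set(rejected)
    if overlap:  # cannot happen with k+q <= n, kept as a guard
        raise AssertionError(f"chosen/rejected overlap: {sorted(overlap)}")
    return PreferenceRecord(pred.sample_id, prompt, chosen, rejected)


def build_sft_record(
    pred: RankedPrediction,
    prompt: str,
    space: LabelSpace,
    template: str = "{label}",
) -> SftRecord:
    """Build a supervised fine-tuning target naming the true label once."""
    entry = space.lookup(pred.true_label)
    if entry.abbreviation:
        rendered = template.format(label=f"{entry.canonical_name} ({entry.abbreviation})")
    else:
        rendered = template.format(label=entry.canonical_name)
    return SftRecord(pred.sample_id, prompt, rendered)


def aor_of(k: int, q: int) -> float:
    """Acceptance-over-rejection ratio k/q."""
    if q < 1:
        raise ValueError(f"q must be >=1, got {q}")
    return k / q


def build_dataset(
    preds: Iterable[RankedPrediction],
    prompts: Mapping[str, str],
    space: LabelSpace,
    k: int,
    q: int,
) -> list[PreferenceRecord]:
    """Build one preference record per prediction, input order preserved."""
    records: list[PreferenceRecord] = []
    for pred in preds:
        if pred.sample_id not in prompts:
            raise KeyError(f"no prompt for sample {pred.sample_id!r}")
        records.append(build_preference_record(pred, prompts[pred.sample_id], space, k, q))
    logger.info(
        "built %d preference records (k=%d, q=%d, AoR=%.4g)",
        len(records), k, q, aor_of(k, q),
    )
    return records


# --- JSONL interfaces ------------------------------------------------------

def read_rankings_jsonl(path) -> list[RankedPrediction]:
    """Read ``{id, scores: {name: prob}, true_label}`` objects, one per line."""
    out: list[RankedPrediction] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "_meta" in obj:
                continue
            out.append(RankedPrediction(obj["id"], dict(obj["scores"]), obj["true_label"]))
    return out


def write_preferences_jsonl(records: Sequence[PreferenceRecord], path, meta: Optional[dict] = None) -> None:
    """Write preference records; chosen/rejected as arrays and numbered text."""
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write(json.dumps({"_meta": meta}, sort_keys=True) + "\n")
        for r in records:
            fh.write(json.dumps({
                "id": r.sample_id,
                "prompt": r.prompt,
                "chosen": r.chosen,
                "rejected": r.rejected,
                "chosen_text": r.chosen_text,
                "rejected_text": r.rejected_text,
            }, sort_keys=True) + "\n")
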