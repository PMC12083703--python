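"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the
package: a recursive Ratcliff/Obershelp ratio, a materialized-sort
preference-pair builder, and an exact (multi)set-arithmetic grader.
"""

from collections import Counter


def ro_matches(a: str, b: str) -> int:
    """Total matched characters via recursive longest-matching-block."""
    best_i = best_j = best_k = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best_k:
                best_i, best_j, best_k = i, j, k
    if best_k == 0:
        return 0
    return (
        best_k
        + ro_matches(a[:best_i], b[:best_j])
        + ro_matches(a[best_i + best_k:], b[best_j + best_k:])
    )


def ro_ratio(a: str, b: str) -> float:
    """Reference Ratcliff/Obershelp similarity 2M/T."""
    if not a and not b:
        return 1.0
    return 2.0 * ro_matches(a, b) / (len(a) + len(b))


def brute_preference_pair(scores: dict, label_ids: dict, truth: str, k: int, q: int):
    """Materialize the full sorted list and apply the stated rules naively."""
    ranked = sorted(scores, key=lambda n: (-scores[n], label_ids[n]))
    top = ranked[:k]
    if truth in top:
        i = top.index(truth)
        chosen = [truth] + top[1:i] + [top[0]] + top[i + 1:] if i else list(top)
    else:
        chosen = [truth] + top[:k - 1]
    rejected = ranked[-q:][::-1]
    if truth in rejected:
        rejected.remove(truth)
        for cand in ranked[::-1]:
            if cand not in chosen and cand not in rejected:
                rejected.append(cand)
                break
    return chosen, rejected


def exact_match_count(names, pool) -> int:
    """Multiset intersection size on normalized strings."""

    def norm(s):
        return " ".join(s.split()).casefold().rstrip(".").rstrip()

    return sum((Counter(map(norm, names)) & Counter(map(norm, pool))).values())


def brute_evaluate(instances, lambda_weight=1.0):
    """Grade instances with exact string matching and plain set arithmetic.

    Each instance: dict with names (response list), labels (vocabulary),
    truth, top_k, bottom_q. Returns (hfa%, topn%, top1%, car).
    """

    def norm(s):
        return " ".join(s.split()).casefold().rstrip(".").rstrip()

    n = len(instances)
    hfa = topn = top1 = 0
    car_total = 0.0
    for inst in instances:
        names = inst["names"]
        vocab = {norm(l) for l in inst["labels"]}
        ok = bool(names) and all(norm(x) in vocab for x in names)
        hfa += ok
        if ok:
            truth = norm(inst["truth"])
            firstn = [norm(x) for x in names[: inst["n_top"]]]
            topn += truth in firstn
            top1 += bool(firstn) and firstn[0] == truth
        if names:
            c = exact_match_count(names, inst["top_k"]) / len(names)
            a = 1.0 - exact_match_count(names, inst["bottom_q"]) / len(names)
        else:
            c = a = 0.0
        denom = lambda_weight * c + a
        car_total += (1 + lambda_weight) * c * a / denom if denom > 0 else 0.0
    return 100.0 * hfa / n, 100.0 * topn / n, 100.0 * top1 / n, car_total / n
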