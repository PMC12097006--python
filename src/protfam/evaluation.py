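"""Taxonomic-profile evaluation against gold standards.

Presence/absence metrics (TP/FP/FN, sensitivity, precision, accuracy,
F1, Jaccard) compare the predicted and true species sets under a
matching key (taxid preferred, normalized name otherwise); the L1 norm
additionally compares relative abundances on renormalized vectors and
ranges over [0, 2].  The cross-sample frequency analysis counts, per
metric, how often each database/threshold combination attains the best
score over the sample panel (ties credit every winner).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import IO, Hashable, Iterable

from .krakenroute import AbundanceProfile

# Metrics where the best score is the highest vs. the lowest.
HIGHER_IS_BETTER = {"tp", "sensitivity", "precision", "accuracy", "f1", "jaccard"}
LOWER_IS_BETTER = {"fp", "fn", "l1_norm"}

_STRAIN_RE = re.compile(r"\s+(str|substr)\.\s+.*$")


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    accuracy: float
    f1: float
    jaccard: float
    l1_norm: float | None = None


def normalize_name(name: str) -> str:
    """Lowercase, collapse whitespace, strip strain/substrain suffixes."""
    name = re.sub(r"\s+", " ", name.strip().lower())
    return _STRAIN_RE.sub("", name)


def _keys(profile: AbundanceProfile, key: str) -> dict[Hashable, float]:
    out: dict[Hashable, float] = {}
    for name, taxid, _reads, fraction in profile.records:
        k: Hashable = taxid if key == "taxid" else normalize_name(name)
        if k in out:
            raise ValueError(f"duplicate {key} within profile: {k!r}")
        out[k] = fraction
    return out


def match_species(predicted: AbundanceProfile, gold: AbundanceProfile,
                  key: str = "taxid") -> tuple[set, set, set]:
    """(tp, fp, fn) key sets: intersection, predicted-only, gold-only."""
    if key not in ("taxid", "normalized_name"):
        raise ValueError("key must be 'taxid' or 'normalized_name'")
    p = set(_keys(predicted, key))
    g = set(_keys(gold, key))
    return p & g, p - g, g - p


def compute_metrics(tp: int, fp: int, fn: int,
                    universe_size: int | None = None) -> EvalResult:
    """Presence/absence metrics from count triples.

    Accuracy uses true negatives when an evaluation universe is given
    (tn = universe - tp - fp - fn); without one it falls back to the
    Jaccard index.  Zero denominators yield 0; the empty triple yields
    all-zero metrics.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    jac = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    if universe_size is not None:
        if universe_size < tp + fp + fn:
            raise ValueError("universe smaller than tp+fp+fn")
        tn = universe_size - tp - fp - fn
        denom = tp + tn + fp + fn
        acc = (tp + tn) / denom if denom else 0.0
    else:
        acc = jac
    return EvalResult(tp=tp, fp=fp, fn=fn, sensitivity=sens, precision=prec,
                      accuracy=acc, f1=f1, jaccard=jac)


def l1_norm(predicted: AbundanceProfile, gold: AbundanceProfile,
            key: str = "taxid") -> float:
    """Sum over the species union of |p_hat - p|, each profile
    renormalized to sum 1 and missing species contributing 0."""
    p = _keys(predicted, key)
    g = _keys(gold, key)
    if not p and not g:
        raise ValueError("both profiles are empty")
    pt, gt = sum(p.values()), sum(g.values())
    total = 0.0
    for k in set(p) | set(g):
        pv = p.get(k, 0.0) / pt if pt else 0.0
        gv = g.get(k, 0.0) / gt if gt else 0.0
        total += abs(pv - gv)
    return total


def evaluate_profile(predicted: AbundanceProfile, gold: AbundanceProfile,
                     key: str = "taxid",
                     universe_size: int | None = None) -> EvalResult:
    """Full metric suite for one predicted profile vs. its gold standard."""
    tp, fp, fn = match_species(predicted, gold, key)
    result = compute_metrics(len(tp), len(fp), len(fn), universe_size)
    result.l1_norm = l1_norm(predicted, gold, key)
    return result


def best_combination_frequency(scores: dict[tuple[str, str], float],
                               metric: str) -> dict[str, int]:
    """Per-combination count of samples where it attains the best score.

    *scores* maps (combination, sample) to the metric score; every
    combination must be scored on every sample.  The best score per
    sample is the maximum or the minimum depending on the metric; all
    combinations tying it are credited.
    """
    if metric in HIGHER_IS_BETTER:
        better_max = True
    elif metric in LOWER_IS_BETTER:
        better_max = False
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    by_sample: dict[str, dict[str, float]] = defaultdict(dict)
    combos: set[str] = set()
    for (combo, sample), score in scores.items():
        by_sample[sample][combo] = score
        combos.add(combo)
    for sample, row in by_sample.items():
        if set(row) != combos:
            raise ValueError(f"sample {sample!r} missing combinations")
    freq = {c: 0 for c in combos}
    for row in by_sample.values():
        best = max(row.values()) if better_max else min(row.values())
        for combo, score in row.items():
            if score == best:
                freq[combo] += 1
    return freq


# ---------------------------------------------------------------------------
# Gold-standard I/O and reports
# ---------------------------------------------------------------------------

def read_gold_standard(stream: IO[str] | Iterable[str]) -> AbundanceProfile:
    """Gold-standard TSV: species, taxid, relative_abundance."""
    records: list[tuple[str, int, int, float]] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("species\t") or line.startswith("#"):
            continue
        name, taxid, frac = line.split("\t")
        records.append((name, int(taxid), 0, float(frac)))
    return AbundanceProfile(records=records)


def write_metric_report(results: dict[str, EvalResult], path) -> None:
    """Per-sample metric report TSV."""
    cols = ["tp", "fp", "fn", "sensitivity", "precision", "accuracy",
            "f1", "jaccard", "l1_norm"]
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(cols) + "\n")
        for sample in sorted(results):
            r = results[sample]
            vals = [getattr(r, c) for c in cols]
            fh.write(sample + "\t" +
                     "\t".join("" if v is None else f"{v:.10g}" for v in vals) +
                     "\n")
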