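"""Evaluation against human scores and throughput accounting.

Automatic and human scores are compared after collapsing both to the
four groups crystal / precipitate / other / clear; per-group success
rates are combined into a frequency-weighted mean (each group weighted
by its number of human-scored wells).  Unscored automatic wells count
as mismatches.  Also computes the parallelization factor needed for a
per-well processing time to keep pace with the imaging interval
(16.25 s per well in the standard schedule, down to 5.19 s at maximum
plate load).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classes import ClassScheme, Group, group_of

GROUPS: tuple[Group, ...] = ("crystal", "precipitate", "other", "clear")

#: imaging intervals (seconds per well) of the plate-imaging schedule
STANDARD_INTERVAL_S = 16.25
MAX_RATE_INTERVAL_S = 5.19


@dataclass
class SuccessTable:
    """Per-group match counts/rates and their frequency-weighted mean."""

    n_human: dict[Group, int]
    n_match: dict[Group, int]
    rate: dict[Group, float]  # percent; groups with n_human == 0 omitted
    weighted_mean: float  # percent

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "n_human": self.n_human[g],
                "n_match": self.n_match[g],
                "rate_pct": round(self.rate[g], 2) if g in self.rate else None,
            }
            for g in GROUPS
        ]
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["| Group | n | Matches | Success rate (%) |",
                 "|---|---|---|---|"]
        for g in GROUPS:
            rate = f"{self.rate[g]:.2f}" if g in self.rate else "-"
            lines.append(
                f"| {g} | {self.n_human[g]} | {self.n_match[g]} | {rate} |"
            )
        lines.append(f"| **weighted mean** | | | **{self.weighted_mean:.2f}** |")
        return "\n".join(lines)


def weighted_mean(rates: dict[Group, float], freqs: dict[Group, int]) -> float:
    """Frequency-weighted mean of per-group success rates (percent)."""
    total = sum(freqs.get(g, 0) for g in rates)
    if total <= 0:
        raise ValueError("all-zero frequencies")
    if any(f < 0 for f in freqs.values()):
        raise ValueError("negative frequency")
    return sum(rates[g] * freqs.get(g, 0) for g in rates) / total


def _to_group(score, is_rim: bool = False) -> Group | None:
    if score is None or (isinstance(score, str) and score.upper() == "UNSCORED"):
        return None
    return group_of(int(score), is_rim)


def success_table(
    auto_scores: dict[str, int | None],
    human_scores: dict[str, int],
    scheme: ClassScheme | None = None,
) -> SuccessTable:
    """Compare automatic vs human well scores at the 4-group level.

    Both inputs map well id -> score number; automatic wells may be
    ``None`` (unscored), which counts as a mismatch.  The well-id sets
    must coincide.
    """
    if set(auto_scores) != set(human_scores):
        missing = set(auto_scores) ^ set(human_scores)
        raise ValueError(f"well ids do not match: {sorted(missing)[:5]}")
    n_human = {g: 0 for g in GROUPS}
    n_match = {g: 0 for g in GROUPS}
    for well_id, human in human_scores.items():
        hg = _to_group(human)
        if hg is None:
            raise ValueError(f"human score missing for well {well_id}")
        n_human[hg] += 1
        if _to_group(auto_scores[well_id]) == hg:
            n_match[hg] += 1
    rate = {
        g: 100.0 * n_match[g] / n_human[g] for g in GROUPS if n_human[g] > 0
    }
    return SuccessTable(
        n_human=n_human,
        n_match=n_match,
        rate=rate,
        weighted_mean=weighted_mean(rate, n_human),
    )


def parallelization_required(t_per_well: float, interval: float) -> float:
    """Workers needed so t seconds of compute keeps pace with one image
    every ``interval`` seconds (t/16.25 standard, t/5.19 at maximum
    rate).  Callers round up to schedule whole workers."""
    if t_per_well <= 0 or interval <= 0:
        raise ValueError("times must be positive")
    return t_per_well / interval
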