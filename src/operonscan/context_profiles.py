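"""Per-clade operon-content profiles.

For each clade/class: the fraction of targets whose operon contains at
least one gene of each functional category (per-target presence — several
neighbors of the same category in one operon count once), the fraction of
targets with no operon neighbor at all (operon size 1), and the
operon-size histogram. Reporting applies a cutoff (default: strictly more
than 10% of the clade's targets); the full uncut table is always kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import Operon, ProfileParams, TargetRecord, ValidationError, target_key
from .function_categories import CATEGORY_VOCABULARY, OTHER


@dataclass
class CladeProfile:
    label: str
    n_targets: int
    proportion_by_category: Dict[str, float]
    no_neighbor_fraction: float
    size_histogram: Dict[int, int]


def clade_profile(
    operons: Mapping[tuple, Operon],
    category_sets: Mapping[tuple, Set[str]],
    targets: Sequence[TargetRecord],
    label: str,
) -> CladeProfile:
    """Profile all targets carrying ``label``.

    The denominator of every proportion is the full target count for the
    label, including no-neighbor targets.
    """
    keys = [target_key(t) for t in targets if t.clade_label == label]
    if not keys:
        raise ValidationError(f"no targets with label {label!r}; profile undefined")
    for key in keys:
        if key not in operons or key not in category_sets:
            raise ValidationError(f"target {key} lacks an operon or category set")

    n = len(keys)
    presence: Counter = Counter()
    sizes: Counter = Counter()
    for key in keys:
        sizes[operons[key].size] += 1
        for category in category_sets[key]:
            presence[category] += 1
    proportions = {
        category: presence.get(category, 0) / n
        for category in CATEGORY_VOCABULARY
        if category != OTHER
    }
    return CladeProfile(
        label=label,
        n_targets=n,
        proportion_by_category=proportions,
        no_neighbor_fraction=sizes.get(1, 0) / n,
        size_histogram=dict(sorted(sizes.items())),
    )


def operon_size_distribution(operons: Iterable[Operon]) -> Dict[int, int]:
    """Histogram of operon sizes for a group of operons."""
    histogram: Counter = Counter()
    for operon in operons:
        histogram[operon.size] += 1
    return dict(sorted(histogram.items()))


def profiles_frame(profiles: Sequence[CladeProfile]) -> pd.DataFrame:
    """Full (uncut) profile table: one row per (label, category)."""
    rows = []
    for profile in profiles:
        for category, proportion in profile.proportion_by_category.items():
            rows.append(
                {
                    "label": profile.label,
                    "category": category,
                    "n_targets": profile.n_targets,
                    "proportion": proportion,
                }
            )
        rows.append(
            {
                "label": profile.label,
                "category": "no_neighbor",
                "n_targets": profile.n_targets,
                "proportion": profile.no_neighbor_fraction,
            }
        )
    return pd.DataFrame(rows, columns=["label", "category", "n_targets", "proportion"])


def report_profiles(
    profiles: Sequence[CladeProfile],
    params: ProfileParams = ProfileParams(),
) -> pd.DataFrame:
    """Reported (label, category, proportion) rows passing the cutoff.

    With the strict default, a category at exactly the cutoff (e.g. 0.100)
    is excluded. ``no_neighbor`` rows are informational and bypass the
    cutoff test only through their own proportion like any category.
    """
    frame = profiles_frame(profiles)
    if params.cutoff_strict:
        keep = frame["proportion"] > params.report_cutoff
    else:
        keep = frame["proportion"] >= params.report_cutoff
    return frame[keep].reset_index(drop=True)


def write_profiles(
    profiles: Sequence[CladeProfile],
    params: ProfileParams,
    full_path,
    report_path,
    histogram_path,
) -> None:
    profiles_frame(profiles).to_csv(full_path, sep="\t", index=False)
    report_profiles(profiles, params).to_csv(report_path, sep="\t", index=False)
    rows = []
    for profile in profiles:
        for size, count in profile.size_histogram.items():
            rows.append({"label": profile.label, "operon_size": size, "count": count})
    pd.DataFrame(rows, columns=["label", "operon_size", "count"]).to_csv(
        histogram_path, sep="\t", index=False
    )
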