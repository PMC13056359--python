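"""Isoform counts and conditional co-occurrence probabilities.

The counting unit is the genome assembly. For labels X and Y (CODH clades
A-F, HCP classes I-III, or their union),

    P(X|Y) = N_XY / N_Y,

where N_Y is the number of assemblies containing at least one member of
label Y and N_XY the number containing at least one member of both X and
Y. Presence is thresholded at >= 1 copy; copy numbers only matter for the
isoform-frequency distribution. The matrix is asymmetric whenever the
marginals differ. Columns with N_Y = 0 are undefined and reported as
missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import TargetRecord

#: counts: DataFrame indexed by assembly_id with one integer column per label
AssemblyCladeCounts = pd.DataFrame


def count_by_assembly(
    linked_targets: Iterable[TargetRecord],
    labels: Optional[Sequence[str]] = None,
) -> AssemblyCladeCounts:
    """Count targets per (assembly, clade/class label).

    Every target contributes exactly 1 to exactly one cell. ``labels``
    fixes the column set (missing labels appear as all-zero columns);
    otherwise columns are the labels observed, sorted.
    """
    rows = [
        {"assembly_id": t.assembly_id, "label": t.clade_label}
        for t in linked_targets
    ]
    if not rows:
        return pd.DataFrame(columns=list(labels) if labels else []).astype(int)
    frame = pd.DataFrame(rows)
    counts = (
        frame.groupby(["assembly_id", "label"]).size().unstack(fill_value=0)
    )
    counts.columns.name = None
    if labels is not None:
        counts = counts.reindex(columns=list(labels), fill_value=0)
    else:
        counts = counts.reindex(columns=sorted(counts.columns))
    return counts.astype(int)


def isoform_frequency(counts: AssemblyCladeCounts) -> Dict[str, Dict[int, int]]:
    """Per label, the number of assemblies carrying exactly k copies (k>=1).

    For each label, the frequencies sum to the number of assemblies with at
    least one copy (N_label).
    """
    frequency: Dict[str, Dict[int, int]] = {}
    for label in counts.columns:
        column = counts[label]
        nonzero = column[column >= 1]
        frequency[label] = (
            nonzero.value_counts().sort_index().to_dict() if len(nonzero) else {}
        )
    return frequency


def multi_copy_fraction(counts: AssemblyCladeCounts) -> float:
    """Fraction of assemblies (with >=1 target of any label) that carry
    more than one target in total — e.g. the share of genomes encoding
    multiple CODH isoforms."""
    totals = counts.sum(axis=1)
    totals = totals[totals >= 1]
    if len(totals) == 0:
        return float("nan")
    return float((totals > 1).mean())


@dataclass
class ConditionalProbabilityMatrix:
    """N_Y, N_XY and P(X|Y) over label pairs.

    ``p.loc[x, y]`` is P(X|Y); columns with N_Y = 0 are NaN. The integer
    identity P(X|Y)*N_Y = N_XY = P(Y|X)*N_X holds exactly because both
    probabilities are derived from the same symmetric N_XY table.
    """

    labels_x: tuple
    labels_y: tuple
    n_y: pd.Series  # per label in labels_x ∪ labels_y
    n_xy: pd.DataFrame  # symmetric where both orientations exist
    p: pd.DataFrame  # rows = labels_x, columns = labels_y


def _presence(counts: AssemblyCladeCounts) -> pd.DataFrame:
    return (counts >= 1)


def conditional_probability(
    counts: AssemblyCladeCounts,
    labels_x: Optional[Sequence[str]] = None,
    labels_y: Optional[Sequence[str]] = None,
) -> ConditionalProbabilityMatrix:
    """Conditional co-occurrence matrix P(X|Y) from per-assembly counts."""
    all_labels = list(counts.columns)
    labels_x = list(labels_x) if labels_x is not None else all_labels
    labels_y = list(labels_y) if labels_y is not None else all_labels
    union = list(dict.fromkeys(labels_x + labels_y))

    presence = _presence(counts).reindex(columns=union, fill_value=False)
    n = presence.sum(axis=0).astype(int)  # N_label
    # N_XY via boolean matrix product over assemblies
    joint = presence.T.astype(int) @ presence.astype(int)

    p = pd.DataFrame(index=labels_x, columns=labels_y, dtype=float)
    for y in labels_y:
        if n[y] == 0:
            p[y] = np.nan
        else:
            p[y] = joint.loc[labels_x, y] / n[y]
    return ConditionalProbabilityMatrix(
        labels_x=tuple(labels_x),
        labels_y=tuple(labels_y),
        n_y=n,
        n_xy=joint,
        p=p,
    )


def cross_family_matrix(
    codh_counts: AssemblyCladeCounts, hcp_counts: AssemblyCladeCounts
) -> ConditionalProbabilityMatrix:
    """Cross-family conditional matrix (CODH clades x HCP classes, both
    orientations) over the union of the two assembly universes."""
    combined = codh_counts.join(hcp_counts, how="outer").fillna(0).astype(int)
    return conditional_probability(
        combined,
        labels_x=list(codh_counts.columns) + list(hcp_counts.columns),
        labels_y=list(codh_counts.columns) + list(hcp_counts.columns),
    )


def to_long_frame(matrix: ConditionalProbabilityMatrix) -> pd.DataFrame:
    """Long-format table (X, Y, N_Y, N_XY, P); undefined cells omitted."""
    rows = []
    for y in matrix.labels_y:
        n_y = int(matrix.n_y[y])
        if n_y == 0:
            continue
        for x in matrix.labels_x:
            rows.append(
                {
                    "X": x,
                    "Y": y,
                    "N_Y": n_y,
                    "N_XY": int(matrix.n_xy.loc[x, y]),
                    "P": float(matrix.p.loc[x, y]),
                }
            )
    return pd.DataFrame(rows, columns=["X", "Y", "N_Y", "N_XY", "P"])


def write_matrix(matrix: ConditionalProbabilityMatrix, long_path, wide_path) -> None:
    to_long_frame(matrix).to_csv(long_path, sep="\t", index=False)
    wide = matrix.p.copy()
    wide.index.name = "X\\Y"
    wide.to_csv(wide_path, sep="\t", na_rep=".")
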