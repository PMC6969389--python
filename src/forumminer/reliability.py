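"""Intercoder reliability for the manual labeling step.

Multiple coders independently label the same pilot set of posts; agreement
between them decides whether the rest of the corpus can be split among
coders. Only the average pairwise percent-agreement measure is provided —
the uncorrected statistic the labeling workflow used — and deliberately no
chance-corrected coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

__all__ = ["LabelMatrix", "average_pairwise_percent_agreement", "load_label_matrix"]


@dataclass(frozen=True)
class LabelMatrix:
    """Fully crossed item × coder label assignment.

    Every (item, coder) cell must be present; at least two coders and one
    item are required for a pairwise measure to exist.
    """

    items: tuple[str, ...]
    coders: tuple[str, ...]
    labels: Mapping[tuple[str, str], str]

    def validate(self) -> None:
        if len(self.coders) < 2:
            raise ValueError("need at least 2 coders")
        if not self.items:
            raise ValueError("need at least 1 item")
        missing = [
            (item, coder)
            for item in self.items
            for coder in self.coders
            if (item, coder) not in self.labels
        ]
        if missing:
            raise ValueError(f"missing label cell(s): {missing[:5]}")


def average_pairwise_percent_agreement(m: LabelMatrix) -> float:
    """Unweighted mean, over unordered coder pairs, of percent identical labels.

    For each pair of coders, agreement is 100 × (items labeled identically) /
    (items); the result is the plain mean over all pairs and is invariant
    under permutation of items and of coders. Bounded in [0, 100].
    """
    m.validate()
    n_items = len(m.items)
    pair_scores = []
    for a, b in combinations(m.coders, 2):
        same = sum(1 for item in m.items if m.labels[(item, a)] == m.labels[(item, b)])
        pair_scores.append(100.0 * same / n_items)
    return sum(pair_scores) / len(pair_scores)


def load_label_matrix(path) -> LabelMatrix:
    """Read a labels TSV: ``item_id`` column then one column per coder."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "item_id" not in frame.columns:
        raise ValueError("labels file missing column: item_id")
    coders = tuple(c for c in frame.columns if c != "item_id")
    items = tuple(frame["item_id"])
    labels = {
        (row["item_id"], coder): row[coder]
        for _, row in frame.iterrows()
        for coder in coders
    }
    return LabelMatrix(items=items, coders=coders, labels=labels)
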