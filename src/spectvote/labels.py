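"""Reference-standard labels from multi-reader votes.

Three aggregation schemes turn a scan's binary reader votes into the
training target:

* majority vote (MVT) — the consensus class, hiding reader discrepancy;
* random vote (RVT) — one reader's vote drawn uniformly at each
  presentation from a single run-level stream, so a discrepant scan can
  appear with different labels across epochs;
* average vote (AVT) — the proportion of "reduced" votes, a fractional
  target in {k/R}.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ReaderVotes


class Method(str, enum.Enum):
    MVT = "MVT"
    RVT = "RVT"
    AVT = "AVT"


@dataclass(frozen=True)
class ReferenceLabel:
    value: float
    method: Method


#: tie-break label for even reader panels ("reduced" is the clinically
#: conservative call); never triggered for an odd number of readers
EVEN_TIE_LABEL = 1


def majority_vote(votes: ReaderVotes) -> ReferenceLabel:
    n_reduced = sum(votes)
    r = len(votes)
    if 2 * n_reduced == r:
        value = EVEN_TIE_LABEL
    else:
        value = int(2 * n_reduced > r)
    return ReferenceLabel(float(value), Method.MVT)


def random_vote(votes: ReaderVotes, rng: np.random.Generator) -> ReferenceLabel:
    """One vote chosen uniformly from the shared run-level stream.

    The stream is seeded once per training run and advanced at every
    presentation, never reset between epochs.
    """
    if len(votes) < 2:
        raise ValueError("random-vote aggregation needs at least 2 readers")
    return ReferenceLabel(float(votes.votes[rng.integers(len(votes))]), Method.RVT)


def average_vote(votes: ReaderVotes) -> ReferenceLabel:
    if len(votes) < 1:
        raise ValueError("empty vote tuple")
    return ReferenceLabel(sum(votes) / len(votes), Method.AVT)


def labels_table(records, methods=(Method.MVT, Method.AVT)) -> pd.DataFrame:
    """Deterministic aggregated labels per scan (RVT is drawn at train time)."""
    rows = []
    for rec in records:
        for method in methods:
            agg = majority_vote(rec.votes) if method is Method.MVT else average_vote(rec.votes)
            rows.append({"scan_id": rec.scan_id, "method": method.value, "value": agg.value})
    return pd.DataFrame(rows)
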