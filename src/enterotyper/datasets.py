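"""Bundled worked example: a 36-sample MZ twin cohort with known summaries.

The example encodes, programmatically, a cohort of 10 monozygotic twin
pairs in which 8 pairs were sampled at two time points and 2 pairs at one
(36 samples, 18 paired observations, 16 longitudinal subjects), together
with enterotype and functional-cluster assignments whose summary
arithmetic is known exactly:

* twin concordance 13/18 paired observations (72.2%), of which 5 pairs
  share enterotype 1 and 8 share enterotype 2;
* 5 discordant paired observations from 4 pairs (3 pairs at one time
  point, 1 pair at both);
* persistency 13/16 longitudinal subjects (81.3%);
* 15/36 samples (41.7%) in enterotype 1, 21/36 (58.3%) in enterotype 2;
* functional cluster 1 holds 8 samples (22.2%), all enterotype 1;
  functional cluster 2 holds the other 28 (77.8%) — 7 enterotype-1 plus
  all 21 enterotype-2 samples.

It is the reference fixture for the concordance, persistency and
cross-tabulation operations.
"""

from __future__ import annotations

import pandas as pd

from .io_core import TwinDesign

# per pair: {time_point: (enterotype_A, enterotype_B)}
_PAIR_STATES: dict[str, dict[int, tuple[int, int]]] = {
    "P01": {1: (1, 2), 2: (2, 1)},  # discordant at both times; both twins switch
    "P02": {1: (1, 1), 2: (2, 1)},  # concordant E1 at t1; twin A switches
    "P03": {1: (1, 1), 2: (1, 1)},
    "P04": {1: (1, 1), 2: (1, 1)},
    "P05": {1: (2, 2), 2: (2, 2)},
    "P06": {1: (2, 2), 2: (2, 2)},
    "P07": {1: (2, 2), 2: (2, 2)},
    "P08": {1: (2, 2), 2: (2, 2)},
    "P09": {1: (1, 2)},  # single-time pairs, discordant
    "P10": {1: (1, 2)},
}

# functional cluster 1 = the consistently enterotype-1 pairs
_FUNCTIONAL_CLUSTER_1_PAIRS = ("P03", "P04")


def load_twin_example() -> tuple[TwinDesign, pd.Series, pd.Series]:
    """Return ``(design, enterotype_labels, functional_cluster_labels)``."""
    rows = []
    enterotypes = {}
    functional = {}
    for pair_id, times in _PAIR_STATES.items():
        for tp, (e_a, e_b) in times.items():
            for twin, e in (("A", e_a), ("B", e_b)):
                subject = f"{pair_id}{twin}"
                sample = f"{subject}T{tp}"
                rows.append((sample, subject, pair_id, tp))
                enterotypes[sample] = e
                functional[sample] = 1 if pair_id in _FUNCTIONAL_CLUSTER_1_PAIRS else 2
    design = TwinDesign(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "pair_id", "time_point"])
    )
    labels = pd.Series(enterotypes, name="enterotype")
    fc = pd.Series(functional, name="functional_cluster")
    return design, labels, fc
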