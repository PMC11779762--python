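"""Reference values from the motivating drawing study.

The study presented 24 scatterplot problems (3 generating functions x 2
numbers of points x 2 scales x 2 replicates) to 177 observers and clustered
each problem's fitted log-hyperparameters with the Dirichlet-process
mixture. The per-problem cluster membership counts reported there are
shipped here so the downstream cluster-count ANOVA can be run without the
original drawings, together with the published 2-D decision boundary
separating linear from data-tracking drawings in
(log length scale, log noise variance) space.
"""

from __future__ import annotations

import pandas as pd

from .classify import LinearBoundary

__all__ = [
    "REFERENCE_CLUSTER_SIZES",
    "REFERENCE_BOUNDARY",
    "reference_cluster_counts",
]

#: Cluster membership counts per problem, in reported cluster order.
#: Problems are keyed (generator, n_points, scale, replicate). Row sums are
#: at most 177 participants; problems with missing drawings sum lower.
REFERENCE_CLUSTER_SIZES = {
    ("linear", 6, "small", 1): [128, 43, 5, 1],
    ("linear", 6, "small", 2): [88, 65, 19, 2, 2, 1],
    ("linear", 6, "large", 1): [70, 52, 47, 4, 2, 2],
    ("linear", 6, "large", 2): [108, 55, 6, 4, 2, 2],
    ("linear", 24, "small", 1): [114, 45, 10],
    ("linear", 24, "small", 2): [135, 19, 17, 3, 2, 1],
    ("linear", 24, "large", 1): [68, 59, 24, 19, 4, 2, 1],
    ("linear", 24, "large", 2): [110, 22, 22, 11, 7, 2, 2, 1],
    ("quadratic", 6, "small", 1): [114, 44, 10, 5, 2, 2],
    ("quadratic", 6, "small", 2): [114, 42, 17, 2, 2],
    ("quadratic", 6, "large", 1): [102, 68, 3, 2, 2],
    ("quadratic", 6, "large", 2): [99, 78],
    ("quadratic", 24, "small", 1): [171, 4, 2],
    ("quadratic", 24, "small", 2): [176, 1],
    ("quadratic", 24, "large", 1): [105, 57, 8, 4, 2, 1],
    ("quadratic", 24, "large", 2): [120, 35, 21, 1],
    ("cubic", 6, "small", 1): [116, 55, 4, 2],
    ("cubic", 6, "small", 2): [140, 18, 16, 2, 1],
    ("cubic", 6, "large", 1): [121, 39, 9, 4, 2, 1, 1],
    ("cubic", 6, "large", 2): [63, 57, 56, 1],
    ("cubic", 24, "small", 1): [121, 56],
    ("cubic", 24, "small", 2): [150, 18, 7, 2],
    ("cubic", 24, "large", 1): [127, 26, 13, 8, 3],
    ("cubic", 24, "large", 2): [146, 15, 5, 5, 2, 2, 2],
}

#: Published linear-vs-data-tracking boundary on (log length scale,
#: log noise variance): score = -0.94 log(lambda) + 0.35 log(sigma_n^2)
#: + 0.91, with the non-negative side the data-tracking/quadratic region.
REFERENCE_BOUNDARY = LinearBoundary(
    features=("log_length_scale", "log_noise_var"),
    weights=(-0.94, 0.35),
    bias=0.91,
    positive_label="data_tracking",
    training_accuracy=0.8858,
)


def reference_cluster_counts() -> pd.DataFrame:
    """The 24 per-problem cluster counts as a tidy design table.

    Columns: generator, n_points, scale, replicate, n_clusters,
    n_participants (the row sum of the membership counts).
    """
    rows = [
        {
            "generator": g,
            "n_points": n,
            "scale": s,
            "replicate": r,
            "n_clusters": len(sizes),
            "n_participants": sum(sizes),
        }
        for (g, n, s, r), sizes in REFERENCE_CLUSTER_SIZES.items()
    ]
    return pd.DataFrame(rows)
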