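import numpy as np
import pandas as pd
import pytest

from tumorhet import ExpressionMatrix, SampleMap, SurvivalFrame


@pytest.fixture
def two_patient_expr():
    """Hand-checkable 1-gene matrix: P1:{0,2}, P2:{10,12}."""
    em = ExpressionMatrix(
        pd.DataFrame([[0.0, 2.0, 10.0, 12.0]], index=["g1"], columns=list("abcd"))
    )
    sm = SampleMap(
        pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "patient_id": ["P1", "P1", "P2", "P2"],
                "region_id": ["R1", "R2", "R1", "R2"],
            }
        )
    )
    return em, sm


@pytest.fixture
def small_cohort():
    """Random 20-gene, 4-patient x 3-region cohort (seeded)."""
    rng = np.random.default_rng(123)
    n_p, n_r, n_g = 4, 3, 20
    patients = np.repeat([f"P{i}" for i in range(n_p)], n_r)
    samples = [f"P{i}_R{j}" for i in range(n_p) for j in range(n_r)]
    values = rng.normal(8, 1, size=(n_g, n_p * n_r))
    em = ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(n_g)], columns=samples)
    )
    sm = SampleMap(pd.DataFrame({"sample_id": samples, "patient_id": patients}))
    return em, sm


def make_survival(time, event, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(time))]
    return SurvivalFrame(
        pd.DataFrame({"sample_id": ids, "time": time, "event": event})
    )


# ---------------------------------------------------------------------------
# Independent oracles used by several test modules
# ---------------------------------------------------------------------------

def naive_agglomeration_partitions(values, method):
    """Brute-force hierarchical clustering for tiny N, scipy-independent.

    Returns {k: labels array} for every k = 1..N, merging the closest
    cluster pair at each step under the given linkage rule.
    """
    values = np.asarray(values, dtype=float)

    def dist(ca, cb):
        pa, pb = values[ca], values[cb]
        pairs = np.abs(pa[:, None] - pb[None, :])
        if method == "average":
            return pairs.mean()
        if method == "complete":
            return pairs.max()
        if method == "single":
            return pairs.min()
        if method == "ward":  # increase in within-cluster sum of squares
            na, nb = len(ca), len(cb)
            return na * nb / (na + nb) * (pa.mean() - pb.mean()) ** 2
        raise ValueError(method)

    clusters = [[i] for i in range(values.size)]
    out = {}

    def record():
        labels = np.empty(values.size, dtype=int)
        for lab, members in enumerate(clusters):
            labels[members] = lab
        out[len(clusters)] = labels

    record()
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = dist(clusters[a], clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        record()
    return out


def pgor_by_enumeration(values, patients, method):
    """PGOR at every k from the brute-force partitions."""
    patients = np.asarray(patients, dtype=object)
    parts = naive_agglomeration_partitions(values, method)
    blocks = [
        np.flatnonzero(patients == p)
        for p in dict.fromkeys(patients)
        if (patients == p).sum() >= 2
    ]
    n = len(values)
    return np.array(
        [
            sum(1 for blk in blocks if len(set(parts[k][blk])) == 1) / len(blocks)
            for k in range(1, n + 1)
        ]
    )


def balanced_anova_itvs(values, n_groups, group_size):
    """Closed-form balanced one-way ANOVA components for one gene."""
    y = np.asarray(values, dtype=float).reshape(n_groups, group_size)
    group_means = y.mean(axis=1)
    grand = y.mean()
    msw = ((y - group_means[:, None]) ** 2).sum() / (n_groups * (group_size - 1))
    msb = group_size * ((group_means - grand) ** 2).sum() / (n_groups - 1)
    w = msw
    b = max((msb - msw) / group_size, 0.0)
    return w, b, w / (w + b) if w + b > 0 else np.nan


def two_group_logrank_chi2(time, event, group):
    """Textbook two-sample log-rank statistic from explicit risk tables."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g1 = group == np.unique(group)[0]
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
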