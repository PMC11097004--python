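import numpy as np
import pytest

import accelbehave as ab


@pytest.fixture(scope="session")
def default_calibration():
    """The default synthetic calibration set (seed 0): traces + labels."""
    return ab.generate_calibration_set(seed=0)


@pytest.fixture(scope="session")
def default_features40(default_calibration):
    """Extended 40 Hz labelled feature frame of the default calibration set."""
    traces, segments = default_calibration
    return ab.build_bout_features(traces, segments, "extended")


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down experiment config for plumbing tests (not study scale)."""
    cfg = ab.ExperimentConfig(seed=11)
    cfg.calibration.n_individuals = 4
    cfg.calibration.per_behaviour_s = {
        b: s / 8.0 for b, s in ab.DEFAULT_CALIBRATION_S.items()}
    cfg.rf = ab.RFConfig(n_trees=25)
    cfg.deployment.n_deployments = 2
    cfg.deployment.duration_days = 0.03
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately independent of the library implementations


def oracle_running_mean(x, window):
    x = np.asarray(x, dtype=float)
    n = len(x)
    left = window // 2
    right = window - 1 - left
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = sum(x[lo:hi]) / (hi - lo)
    return out


def oracle_running_se(x, window):
    x = np.asarray(x, dtype=float)
    n = len(x)
    left = window // 2
    right = window - 1 - left
    out = np.zeros(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        w = x[lo:hi]
        m = len(w)
        if m >= 2:
            mean = sum(w) / m
            var = sum((v - mean) ** 2 for v in w) / (m - 1)
            out[i] = (var / m) ** 0.5
    return out


def oracle_block_means(x, block):
    x = np.asarray(x, dtype=float)
    n = (len(x) // block) * block
    return np.array([sum(x[i:i + block]) / block for i in range(0, n, block)])


def oracle_confusion_metrics(true, pred, labels):
    """Per-class precision/recall/F from explicit counting."""
    out = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(true, pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(true, pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(true, pred) if t == lab and p != lab)
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        if np.isnan(prec) or np.isnan(rec):
            f = float("nan")
        elif prec + rec == 0:
            f = 0.0
        else:
            f = 2 * prec * rec / (prec + rec)
        out[lab] = (prec, rec, f)
    return out


def oracle_icc_a1(x):
    """ICC(A,1) from first-principles two-way ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in x)
    ss_cols = sum(n * (col.mean() - grand) ** 2 for col in x.T)
    ss_tot = sum((v - grand) ** 2 for v in x.ravel())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
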