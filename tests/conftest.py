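import numpy as np
import pandas as pd
import pytest

from carboxmeta import annotations as anno


@pytest.fixture
def small_annotations() -> pd.DataFrame:
    rows = [
        ("g1", "c1", "KEGG", "K00001", 1e-6),
        ("g1", "c1", "PFAM", "PF00001", 1e-10),
        ("g1", "c1", "PFAM", "PF00002", 1e-9),
        ("g2", "c1", "PFAM", "PF00001", 1e-8),
        ("g2", "c1", "PFAM", "PF00001", 1e-7),  # duplicate (gene, category)
        ("g3", "c2", "COG", "COG1960", 0.5),
        ("g4", "c2", "GH", "GH48", 1e-12),
        ("g5", "c2", "GH", "GH43", 1e-9),
    ]
    return pd.DataFrame(rows, columns=anno.ANNOTATION_COLUMNS)


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values by the definitional min formula:
    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
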