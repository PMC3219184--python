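import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dcismir.config import PipelineConfig
from dcismir.containers import CtMatrix, ExpressionMatrix, SampleAnnotation

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_annotation(n_patients=8, n_pool=3):
    rows = []
    for r in range(n_pool):
        rows.append({"sample_id": f"PRM_r{r + 1}", "group": "PRM",
                     "patient_id": None, "replicate_index": r + 1})
    for group in ("HN", "DCIS"):
        for i in range(n_patients):
            pid = f"P{i + 1:02d}"
            rows.append({"sample_id": f"{group}_{pid}", "group": group,
                         "patient_id": pid, "replicate_index": 1})
    return SampleAnnotation(pd.DataFrame(rows).set_index("sample_id"))


def make_ct(values, n_patients=8, n_pool=3, ct_max=40.0, features=None):
    """values: array (n_features, n_pool + 2*n_patients) ordered PRM, HN, DCIS."""
    ann = make_annotation(n_patients, n_pool)
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"miR-t{i}" for i in range(values.shape[0])]
    cols = ann.sample_ids
    return CtMatrix(values=pd.DataFrame(values, index=features, columns=cols),
                    annotation=ann, ct_max=ct_max)


def make_expr(hn, dcis, gene_map=None, features=None):
    """hn/dcis: arrays (n_probes, n_patients) of log2 values."""
    hn = np.atleast_2d(np.asarray(hn, dtype=float))
    dcis = np.atleast_2d(np.asarray(dcis, dtype=float))
    n = hn.shape[1]
    ann = make_annotation(n_patients=n, n_pool=1)
    if features is None:
        features = [f"probe{i}" for i in range(hn.shape[0])]
    cols = ([f"HN_P{i + 1:02d}" for i in range(n)]
            + [f"DCIS_P{i + 1:02d}" for i in range(n)])
    vals = pd.DataFrame(np.hstack([hn, dcis]), index=features, columns=cols)
    if gene_map is None:
        gene_map = pd.Series({f: f"G_{f}" for f in features})
    return ExpressionMatrix(values=vals, annotation=ann, gene_map=gene_map,
                            present=pd.DataFrame(True, index=vals.index,
                                                 columns=vals.columns))


@pytest.fixture
def annotation():
    return make_annotation()
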