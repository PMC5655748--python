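"""Small input-handling helpers shared by the estimators."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TripletDataset


def unpack_triplet(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce estimator input to the ``(g, x, y)`` triple.

    Accepts a :class:`~causaltrio.simulate.TripletDataset`, a DataFrame
    with columns ``g, x, y``, or an ``(n, 3)`` array whose columns are
    genotype, mediator, outcome in that order.
    """
    if isinstance(X, TripletDataset):
        return X.triplet()
    if isinstance(X, pd.DataFrame):
        missing = {"g", "x", "y"} - set(X.columns)
        if missing:
            raise ValueError(f"DataFrame input lacks columns {sorted(missing)}")
        return (X["g"].to_numpy(dtype=float), X["x"].to_numpy(dtype=float),
                X["y"].to_numpy(dtype=float))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of [g, x, y], got shape {arr.shape}")
    return arr[:, 0], arr[:, 1], arr[:, 2]
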