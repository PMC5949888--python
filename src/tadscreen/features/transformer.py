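"""scikit-learn transformer exposing the feature catalog."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import FeatureDef, build_default_catalog, compute_feature


class PeptideFeaturizer(TransformerMixin, BaseEstimator):
    """Encode peptides into the 146-feature default matrix.

    A stateless transformer (fit only resolves the catalog) that maps an
    iterable of peptide strings to a DataFrame with one column per
    feature_id, composable with sklearn pipelines.

    Parameters
    ----------
    catalog : list of FeatureDef, optional
        Feature definitions; the bundled default catalog when omitted.
    """

    def __init__(self, catalog: list[FeatureDef] | None = None):
        self.catalog = catalog

    def fit(self, X, y=None):
        self.catalog_ = (
            list(self.catalog) if self.catalog is not None else build_default_catalog()
        )
        self.feature_names_ = [d.feature_id for d in self.catalog_]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            self.fit(X)
        rows = [[compute_feature(p, d) for d in self.catalog_] for p in X]
        return pd.DataFrame(rows, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
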