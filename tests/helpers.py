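"""Shared test helpers (importable because pytest puts tests/ on sys.path)."""

import pandas as pd

from stppinet.datatypes import ExpressionMatrix


def matrix_from(values: dict[str, list[float]]) -> ExpressionMatrix:
    """Expression matrix from {gene: values} with dummy one-interval metadata."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame({"stage": 1, "structure": "AMY"}, index=df.columns)
    return ExpressionMatrix(df, meta)
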