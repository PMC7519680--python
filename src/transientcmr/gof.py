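"""Goodness-of-fit components that detect transience.

Test 3.SR asks, among animals encountered at occasion ``t``, whether those
encountered for the *first* time are re-encountered later at the same rate
as those already known.  A directional deficit of re-encounters among new
animals is the signature of transients.  Test 3.Sm is the companion memory
test on previously encountered animals only: does time since the previous
encounter predict future re-encounter?  Their summed chi-square over the
summed degrees of freedom is the variance-inflation (overdispersion)
factor c-hat used to correct model selection.

Sparse-cell policy: when any expected cell of an occasion table falls below
2, that occasion's contribution is computed from Fisher's exact test
(converted to a 1-df chi-square deviate) rather than the Pearson statistic;
the per-occasion method is recorded in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encounter import EncounterDataset

__all__ = ["GofComponent", "test_3sr", "test_3sm", "estimate_chat"]

_SPARSE_EXPECTED = 2.0


@dataclass
class GofComponent:
    """One goodness-of-fit component (3.SR or 3.Sm).

    ``tables`` holds the per-occasion observed counts and statistics;
    ``chi2``/``df``/``p_value`` the pooled component; ``directional_z``
    (3.SR only) the signed normal statistic from the occasion-summed 2x2
    table, positive when newly encountered animals are re-seen *less*
    often than previously encountered ones (the transience direction).
    ``undefined`` flags a component with no informative table.
    """

    name: str
    tables: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    directional_z: float | None = None
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "directional_z": self.directional_z,
            "undefined": self.undefined,
        }


def _pearson_2xc(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square and df for an r x c table with margins > 0."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = rows @ cols / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def _informative(table: np.ndarray) -> bool:
    return bool((table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all())


def _occasion_statistic(table: np.ndarray) -> tuple[float, int, str]:
    """(chi2 contribution, df, method) for one occasion's 2x2 table."""
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    if (expected < _SPARSE_EXPECTED).any():
        _, p = stats.fisher_exact(table)
        p = min(max(p, 1e-300), 1.0)
        return float(stats.chi2.isf(p, 1)), 1, "fisher"
    chi2, df = _pearson_2xc(table)
    return chi2, df, "pearson"


def _first_detection(hist: np.ndarray) -> np.ndarray:
    """Index of each individual's first detection."""
    return np.argmax(hist, axis=1)


def _3sr_tables(hist: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Per-interior-occasion 2x2 tables [new/old] x [reseen/never]."""
    n, K = hist.shape
    first = _first_detection(hist)
    seen_after = np.zeros((n, K), dtype=bool)
    if K > 1:
        seen_after[:, :-1] = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1][:, 1:] > 0
    out = []
    for t in range(1, K - 1):
        at_t = hist[:, t] == 1
        new = at_t & (first == t)
        old = at_t & (first < t)
        table = np.array(
            [
                [int((new & seen_after[:, t]).sum()), int((new & ~seen_after[:, t]).sum())],
                [int((old & seen_after[:, t]).sum()), int((old & ~seen_after[:, t]).sum())],
            ]
        )
        out.append((t, table))
    return out


def test_3sr(data: EncounterDataset, by_group: bool = False):
    """Transience component of the goodness-of-fit test (3.SR).

    For each interior occasion ``t``, animals encountered at ``t`` are
    cross-classified as {newly encountered, previously encountered} x
    {re-encountered after ``t``, never again}; occasion chi-squares are
    summed, and a signed z from the occasion-summed table gives the
    direction (positive = transience).

    With ``by_group=True`` returns a dict with the pooled component under
    ``"pooled"`` and one component per group label, mirroring per-age-class
    GOF testing.

    Raises
    ------
    ValueError
        Fewer than 3 occasions (the test is not applicable).
    """
    if data.n_occasions < 3:
        raise ValueError("test 3.SR requires at least 3 occasions")
    if by_group:
        out = {"pooled": test_3sr(data, by_group=False)}
        for g in data.groups:
            sub = EncounterDataset(
                data.occasions,
                [ind for ind in data.individuals if ind.group == g],
                groups=data.groups,
            ) if any(ind.group == g for ind in data.individuals) else None
            if sub is not None:
                out[g] = test_3sr(sub, by_group=False)
        return out

    hist = data.history_matrix() if data.individuals else np.zeros((0, data.n_occasions), dtype=np.int8)
    rows = []
    chi2_sum, df_sum = 0.0, 0
    pooled = np.zeros((2, 2), dtype=np.int64)
    for t, table in _3sr_tables(hist):
        if _informative(table):
            pooled += table
        rec = {
            "occasion": t + 1,
            "new_reseen": table[0, 0], "new_never": table[0, 1],
            "old_reseen": table[1, 0], "old_never": table[1, 1],
        }
        if _informative(table):
            chi2, df, method = _occasion_statistic(table)
            chi2_sum += chi2
            df_sum += df
            rec.update(chi2=chi2, df=df, method=method)
        else:
            rec.update(chi2=np.nan, df=0, method="empty")
        rows.append(rec)
    tables = pd.DataFrame(rows)
    if df_sum == 0:
        return GofComponent("3.SR", tables, np.nan, 0, np.nan, None, undefined=True)
    p_value = float(stats.chi2.sf(chi2_sum, df_sum))
    z = _directional_z(pooled)
    return GofComponent("3.SR", tables, float(chi2_sum), int(df_sum), p_value, z)


def _directional_z(pooled: np.ndarray) -> float:
    """Signed sqrt of the pooled 2x2 chi-square; positive when new animals
    are under-re-encountered relative to independence."""
    if not _informative(pooled):
        return 0.0
    chi2, _ = _pearson_2xc(pooled)
    expected_new_reseen = pooled[0].sum() * pooled[:, 0].sum() / pooled.sum()
    sign = 1.0 if pooled[0, 0] < expected_new_reseen else (-1.0 if pooled[0, 0] > expected_new_reseen else 0.0)
    return float(sign * np.sqrt(chi2))


def test_3sm(data: EncounterDataset, max_lag: int = 3) -> GofComponent:
    """Memory component of the goodness-of-fit test (3.Sm).

    Among previously encountered animals seen at occasion ``t``, time since
    the previous encounter (1, 2, ..., ``max_lag``+ years, sparse rows
    collapsed) is cross-classified against re-encounter after ``t``.
    Under the memoryless CJS model the two are independent.

    Raises
    ------
    ValueError
        Fewer than 4 occasions.
    """
    if data.n_occasions < 4:
        raise ValueError("test 3.Sm requires at least 4 occasions")
    hist = data.history_matrix() if data.individuals else np.zeros((0, data.n_occasions), dtype=np.int8)
    n, K = hist.shape
    first = _first_detection(hist)
    seen_after = np.zeros((n, K), dtype=bool)
    seen_after[:, :-1] = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1][:, 1:] > 0
    # previous detection occasion before t, per individual
    rows = []
    chi2_sum, df_sum = 0.0, 0
    prev = np.full(n, -1)
    for t in range(K - 1):
        if t > 0:
            at_t = hist[:, t] == 1
            old = at_t & (first < t)
            if old.any() and t >= 2:
                lag = np.minimum(t - prev[old], max_lag)
                reseen = seen_after[old, t]
                lags_present = np.unique(lag)
                table = np.array(
                    [
                        [int(((lag == L) & reseen).sum()), int(((lag == L) & ~reseen).sum())]
                        for L in lags_present
                    ]
                )
                keep = table.sum(axis=1) > 0
                table = table[keep]
                rec = {"occasion": t + 1, "n": int(old.sum())}
                if table.shape[0] >= 2 and _informative(table):
                    chi2, df = _pearson_2xc(table)
                    chi2_sum += chi2
                    df_sum += df
                    rec.update(chi2=chi2, df=df, method="pearson")
                else:
                    rec.update(chi2=np.nan, df=0, method="empty")
                rows.append(rec)
        prev[hist[:, t] == 1] = t
    tables = pd.DataFrame(rows)
    if df_sum == 0:
        return GofComponent("3.Sm", tables, np.nan, 0, np.nan, undefined=True)
    p_value = float(stats.chi2.sf(chi2_sum, df_sum))
    return GofComponent("3.Sm", tables, float(chi2_sum), int(df_sum), p_value)


def estimate_chat(components: list[GofComponent]) -> tuple[float, dict[str, float]]:
    """Overdispersion factor c-hat = sum(chi2) / sum(df) over components,
    with each component's fraction of the total lack of fit.

    Raises
    ------
    ValueError
        Total df is zero (c-hat undefined).
    """
    usable = [c for c in components if not c.undefined and c.df > 0]
    total_df = sum(c.df for c in usable)
    if total_df == 0:
        raise ValueError("c-hat undefined: total degrees of freedom is zero")
    total_chi2 = sum(c.chi2 for c in usable)
    fractions = {c.name: c.chi2 / total_chi2 for c in usable} if total_chi2 > 0 else {
        c.name: 0.0 for c in usable
    }
    return total_chi2 / total_df, fractions
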