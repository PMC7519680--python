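"""Encounter-history data model and I/O.

Individual detection histories (one binary vector per animal over a fixed
calendar of sampling occasions) are the raw material of open-population
capture-mark-recapture analysis.  This module holds the in-memory container
(:class:`EncounterDataset`), readers/writers for the MARK-style ``.inp``
dialect and a long-format CSV, the transformation that restricts histories
to the adult (breeding) portion of life, and the reduction to the m-array
sufficient statistic split by time-since-marking class
(:class:`MArray`).

Conventions
-----------
Occasions are 0-indexed internally and 1-indexed in reports.  An interval is
labelled by its left occasion, so interval ``t`` spans occasions ``t`` to
``t + 1``.  The first ``1`` of a history is the animal's release (marking)
occasion.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed set of age-at-first-breeding classes; ages above 7 collapse to "7plus".
AGE_GROUPS = ("3", "4", "5", "6", "7plus")

#: Minimum age at which recruitment to the breeding class can occur.
MIN_BREEDING_AGE = 3

NEWLY_MARKED = "newly_marked"
PREVIOUSLY_MARKED = "previously_marked"
MARK_CLASSES = (NEWLY_MARKED, PREVIOUSLY_MARKED)


class ParseError(ValueError):
    """Raised when an input file does not follow the expected dialect."""


class SchemaError(ValueError):
    """Raised when a file is well formed but disagrees with the declared schema."""


def age_to_group(age: int) -> str:
    """Map an age at first breeding (years) to its class label.

    Ages of 7 years and above collapse to ``"7plus"``.  Ages below the
    recruitment threshold (3 years) are invalid.
    """
    if age < MIN_BREEDING_AGE:
        raise ValueError(
            f"age at first breeding must be >= {MIN_BREEDING_AGE}, got {age}"
        )
    return "7plus" if age >= 7 else str(age)


@dataclass(frozen=True)
class Individual:
    """One marked animal: opaque id, age-class label, binary detection vector."""

    id: str
    group: str
    detections: tuple[int, ...]

    def __post_init__(self) -> None:
        if not any(self.detections):
            raise ValueError(f"individual {self.id!r}: all-zero detection history")
        if any(d not in (0, 1) for d in self.detections):
            raise ValueError(f"individual {self.id!r}: non-binary detections")

    @property
    def release_occasion(self) -> int:
        """0-indexed occasion of the first detection."""
        return self.detections.index(1)

    @property
    def detection_occasions(self) -> tuple[int, ...]:
        return tuple(i for i, d in enumerate(self.detections) if d)


@dataclass
class EncounterDataset:
    """A set of individual encounter histories on a shared occasion calendar.

    Parameters
    ----------
    occasions
        Ordered occasion labels (e.g. years).
    individuals
        The marked animals.  Every history must contain at least one
        detection and have length ``len(occasions)``.
    covariate
        Optional per-occasion environmental series (density-dependence
        proxy); must have one value per occasion.
    groups
        The admissible group labels, in order.  Defaults to the five
        age-at-first-breeding classes.
    """

    occasions: tuple[str, ...]
    individuals: list[Individual]
    covariate: np.ndarray | None = None
    groups: tuple[str, ...] = AGE_GROUPS

    def __post_init__(self) -> None:
        self.occasions = tuple(str(o) for o in self.occasions)
        K = len(self.occasions)
        for ind in self.individuals:
            if len(ind.detections) != K:
                raise ValueError(
                    f"individual {ind.id!r}: history length {len(ind.detections)} "
                    f"!= number of occasions {K}"
                )
            if ind.group not in self.groups:
                raise ValueError(
                    f"individual {ind.id!r}: unknown group {ind.group!r}; "
                    f"expected one of {self.groups}"
                )
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if self.covariate.shape != (K,):
                raise ValueError(
                    f"covariate length {self.covariate.shape} != occasion count {K}"
                )

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    def __len__(self) -> int:
        return len(self.individuals)

    def group_sizes(self) -> dict[str, int]:
        out = {g: 0 for g in self.groups}
        for ind in self.individuals:
            out[ind.group] += 1
        return out

    def history_matrix(self) -> np.ndarray:
        """(n_individuals, n_occasions) 0/1 array."""
        return np.array([ind.detections for ind in self.individuals], dtype=np.int8)

    def single_sighting_fraction(self) -> float:
        """Fraction of histories containing exactly one detection."""
        if not self.individuals:
            return float("nan")
        m = self.history_matrix()
        return float((m.sum(axis=1) == 1).mean())

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (individual, occasion) detection flag."""
        rows = []
        for ind in self.individuals:
            for occ, det in zip(self.occasions, ind.detections):
                rows.append((ind.id, ind.group, occ, det))
        return pd.DataFrame(rows, columns=["id", "group", "occasion", "detected"])


# ---------------------------------------------------------------------------
# MARK-style .inp dialect
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.S)


def read_inp(
    path_or_buffer,
    group_labels: Sequence[str] = AGE_GROUPS,
    occasions: Sequence[str] | None = None,
) -> EncounterDataset:
    """Read a MARK-style ``.inp`` file into an :class:`EncounterDataset`.

    Dialect: one record per line — a 0/1 history string, whitespace, one
    integer frequency column per group, a terminating ``;``.  ``/* */``
    comments and blank lines are ignored.  A frequency of ``f`` in group
    column ``k`` expands to ``f`` individuals with identical histories in
    group ``group_labels[k]``.

    Raises
    ------
    ParseError
        Malformed line (wrong history length, non-binary character,
        missing ``;``), with the 1-based line number.
    SchemaError
        Frequency column count differs from ``len(group_labels)``.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            text = fh.read()
    text = _COMMENT_RE.sub("", text)

    group_labels = tuple(group_labels)
    individuals: list[Individual] = []
    hist_len: int | None = None
    serial = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise ParseError(f"line {lineno}: record does not end with ';'")
        fields = line[:-1].split()
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected history and frequencies")
        hist, freqs = fields[0], fields[1:]
        if not set(hist) <= {"0", "1"}:
            raise ParseError(f"line {lineno}: non-binary character in history {hist!r}")
        if hist_len is None:
            hist_len = len(hist)
        elif len(hist) != hist_len:
            raise ParseError(
                f"line {lineno}: history length {len(hist)} != expected {hist_len}"
            )
        if "1" not in hist:
            raise ParseError(f"line {lineno}: all-zero history is not a valid record")
        if len(freqs) != len(group_labels):
            raise SchemaError(
                f"line {lineno}: {len(freqs)} frequency columns for "
                f"{len(group_labels)} groups"
            )
        detections = tuple(int(c) for c in hist)
        for grp, f in zip(group_labels, freqs):
            try:
                n = int(f)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer frequency {f!r}")
            if n < 0:
                raise ParseError(f"line {lineno}: negative frequency {n}")
            for _ in range(n):
                serial += 1
                individuals.append(Individual(f"ind{serial}", grp, detections))
    if hist_len is None:
        raise ParseError("no records found")
    occ = tuple(occasions) if occasions is not None else tuple(
        str(i + 1) for i in range(hist_len)
    )
    return EncounterDataset(occ, individuals, groups=group_labels)


def write_inp(data: EncounterDataset, path_or_buffer) -> None:
    """Write the ``.inp`` dialect, aggregating identical (history, group) records."""
    counts: dict[tuple[str, str], int] = {}
    for ind in data.individuals:
        hist = "".join(str(d) for d in ind.detections)
        counts[(hist, ind.group)] = counts.get((hist, ind.group), 0) + 1
    by_hist: dict[str, dict[str, int]] = {}
    for (hist, grp), n in counts.items():
        by_hist.setdefault(hist, {})[grp] = n
    lines = []
    for hist in sorted(by_hist):
        freqs = " ".join(str(by_hist[hist].get(g, 0)) for g in data.groups)
        lines.append(f"{hist} {freqs};")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(text)
    else:
        with open(path_or_buffer, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_long_csv(path_or_buffer, groups: Sequence[str] = AGE_GROUPS) -> EncounterDataset:
    """Read the long-format CSV (columns: id, group, occasion, detected)."""
    df = pd.read_csv(path_or_buffer, dtype={"id": str, "group": str, "occasion": str})
    required = {"id", "group", "occasion", "detected"}
    if not required <= set(df.columns):
        raise SchemaError(f"long CSV must have columns {sorted(required)}")
    occasions = tuple(dict.fromkeys(df["occasion"]))
    occ_index = {o: i for i, o in enumerate(occasions)}
    individuals = []
    for ind_id, sub in df.groupby("id", sort=False):
        det = [0] * len(occasions)
        for _, row in sub.iterrows():
            det[occ_index[row["occasion"]]] = int(row["detected"])
        group = sub["group"].iloc[0]
        individuals.append(Individual(str(ind_id), group, tuple(det)))
    return EncounterDataset(occasions, individuals, groups=tuple(groups))


def write_long_csv(data: EncounterDataset, path_or_buffer) -> None:
    data.to_long_dataframe().to_csv(path_or_buffer, index=False)


# ---------------------------------------------------------------------------
# Restriction to the breeding portion of life
# ---------------------------------------------------------------------------

def transform_to_first_breeding(
    raw: EncounterDataset,
    age_at_first: Mapping[str, int],
    birth_occasion: Mapping[str, int] | None = None,
) -> EncounterDataset:
    """Left-truncate histories so the first detection is the first breeding event.

    Pre-breeding detections (prospecting visits, natal-colony sightings) bias
    apparent survival downward for young animals, so the analysis discards
    them: each history is zeroed before the animal's first breeding occasion,
    the age-class group is assigned from the age at first breeding (ages >= 7
    map to ``7plus``), and animals never seen breeding are dropped.

    Parameters
    ----------
    raw
        Histories that may include pre-breeding detections.
    age_at_first
        Age (years) at first breeding, per individual id.
    birth_occasion
        Optional 0-indexed occasion of birth per individual (may be
        negative for animals born before the study).  When given, the
        first-breeding occasion is ``birth_occasion + age_at_first`` and
        all earlier detections are zeroed.  When omitted, histories are
        assumed to already start at first breeding and only the group
        assignment is performed.

    Raises
    ------
    ValueError
        ``age_at_first`` below 3 (recruitment starts at 3 years old).
    """
    out: list[Individual] = []
    for ind in raw.individuals:
        if ind.id not in age_at_first:
            raise KeyError(f"no age at first breeding for individual {ind.id!r}")
        age = int(age_at_first[ind.id])
        group = age_to_group(age)  # raises for age < 3
        if birth_occasion is not None:
            first_breeding = int(birth_occasion[ind.id]) + age
        else:
            first_breeding = ind.release_occasion
        det = tuple(
            d if t >= first_breeding else 0 for t, d in enumerate(ind.detections)
        )
        if not any(det):
            continue  # never seen breeding
        out.append(Individual(ind.id, group, det))
    return EncounterDataset(raw.occasions, out, covariate=raw.covariate,
                            groups=raw.groups)


# ---------------------------------------------------------------------------
# m-array reduction
# ---------------------------------------------------------------------------

@dataclass
class MArray:
    """Release/first-recapture summary split by time-since-marking class.

    The sufficient statistic for CJS-type multinomial likelihoods.  For each
    group ``g``, mark class ``c`` (``newly_marked`` at first capture,
    ``previously_marked`` at re-releases) and release occasion ``t``:

    - ``released[g, c, t]`` animals released,
    - ``m[g, c, t, j]`` of them first recaptured at occasion ``j > t``,
    - the remainder never seen again.

    Arrays are indexed ``g`` over ``groups``, ``c`` over
    ``(newly_marked, previously_marked)``, ``t`` over occasions
    ``0 .. K-1`` and ``j`` over occasions ``0 .. K-1`` (cells with
    ``j <= t`` are structurally zero).  Releases at the final occasion are
    retained for bookkeeping but carry no recapture information.
    """

    groups: tuple[str, ...]
    n_occasions: int
    released: np.ndarray  # (G, 2, K)
    m: np.ndarray         # (G, 2, K, K)

    def __post_init__(self) -> None:
        G, K = len(self.groups), self.n_occasions
        self.released = np.asarray(self.released, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.released.shape != (G, 2, K) or self.m.shape != (G, 2, K, K):
            raise ValueError("MArray array shapes inconsistent with groups/occasions")
        if (self.m < 0).any() or (self.released < 0).any():
            raise ValueError("negative counts in m-array")
        tri = np.tril(np.ones((K, K), dtype=bool))
        if self.m[:, :, tri].any():
            raise ValueError("m-array has recaptures at or before release occasion")
        if (self.m.sum(axis=3) > self.released).any():
            raise ValueError(
                "conservation violated: recaptures exceed releases in some cohort"
            )

    @property
    def never_seen_again(self) -> np.ndarray:
        """(G, 2, K) count of released animals never re-encountered."""
        return self.released - self.m.sum(axis=3)

    def pooled(self) -> "MArray":
        """Sum over groups (single-group m-array)."""
        return MArray(
            ("pooled",),
            self.n_occasions,
            self.released.sum(axis=0, keepdims=True),
            self.m.sum(axis=0, keepdims=True),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per cohort: group, class, release occasion (1-indexed),
        released, m(t,j) columns, never_seen_again."""
        K = self.n_occasions
        rows = []
        never = self.never_seen_again
        for gi, g in enumerate(self.groups):
            for ci, c in enumerate(MARK_CLASSES):
                for t in range(K):
                    if self.released[gi, ci, t] == 0:
                        continue
                    row = {
                        "group": g,
                        "mark_class": c,
                        "release_occasion": t + 1,
                        "released": self.released[gi, ci, t],
                    }
                    for j in range(t + 1, K):
                        row[f"m{j + 1}"] = self.m[gi, ci, t, j]
                    row["never_seen_again"] = never[gi, ci, t]
                    rows.append(row)
        return pd.DataFrame(rows)


def build_marray(data: EncounterDataset) -> MArray:
    """Reduce encounter histories to the m-array sufficient statistic.

    Each detection is a release: the first detection opens a
    ``newly_marked`` cohort, every later detection a ``previously_marked``
    cohort.  The first recapture after a release at ``t`` falls in cell
    ``m(t, j)``; a release never followed by a detection counts as never
    seen again.  The reduction is invariant to individual ordering.
    """
    G, K = len(data.groups), data.n_occasions
    gidx = {g: i for i, g in enumerate(data.groups)}
    released = np.zeros((G, 2, K), dtype=np.int64)
    m = np.zeros((G, 2, K, K), dtype=np.int64)
    for ind in data.individuals:
        g = gidx[ind.group]
        occs = ind.detection_occasions
        for k, t in enumerate(occs):
            c = 0 if k == 0 else 1
            released[g, c, t] += 1
            if k + 1 < len(occs):
                m[g, c, t, occs[k + 1]] += 1
    return MArray(data.groups, K, released, m)
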