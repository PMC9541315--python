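"""Reading, validation and transformation of cross-classified test-accuracy data.

A meta-analysis dataset consists of S studies that each report the *full
cross-classification* of T test results: for every joint pattern of
categories, the number of individuals with that pattern.  The model is
specified at the individual level, so the loader expands counts into
individual records (in a canonical deterministic order) while also keeping
the compact pattern representation that the likelihood actually consumes.

Coding conventions: dichotomous tests are 0 (negative) / 1 (positive);
ordinal tests with K categories are 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TestDefinition",
    "CrossClassTable",
    "MetaDataset",
    "load_dataset",
    "dataset_from_patterns",
    "dichotomize",
    "observed_pairwise_correlations",
]


@dataclass(frozen=True)
class TestDefinition:
    """One test in the panel: its name and number of response categories."""

    __test__ = False  # not a pytest class, despite the name

    name: str
    n_categories: int = 2

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError(
                f"test {self.name!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )

    @property
    def is_ordinal(self) -> bool:
        """Tests with more than two categories get ordinal (cutpoint) handling."""
        return self.n_categories > 2

    @property
    def n_cutpoints(self) -> int:
        return self.n_categories - 1

    def legal_codes(self) -> range:
        return range(0, 2) if not self.is_ordinal else range(1, self.n_categories + 1)


@dataclass(frozen=True)
class CrossClassTable:
    """Counts for every observed joint response pattern within one study."""

    study: object
    patterns: np.ndarray  # (R, T) integer codes
    counts: np.ndarray  # (R,) nonnegative integers

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetaDataset:
    """Individual-level responses for S studies of the same T tests.

    ``patterns``/``pattern_counts``/``pattern_study`` give the compact
    cross-classified form; ``responses`` expands it (lazily) to one row per
    individual, sorted by study then pattern.
    """

    tests: list[TestDefinition]
    study_ids: list
    patterns: np.ndarray  # (R, T)
    pattern_counts: np.ndarray  # (R,)
    pattern_study: np.ndarray  # (R,) index into study_ids
    _responses: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate test names: {names}")
        self._validate()

    # -- basic dimensions --------------------------------------------------
    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    @property
    def n_tests(self) -> int:
        return len(self.tests)

    @property
    def study_sizes(self) -> np.ndarray:
        out = np.zeros(self.n_studies, dtype=int)
        np.add.at(out, self.pattern_study, self.pattern_counts)
        return out

    @property
    def n_individuals(self) -> int:
        return int(self.pattern_counts.sum())

    def _validate(self):
        if self.patterns.shape[1] != self.n_tests:
            raise ValueError("pattern width does not match number of tests")
        if np.any(self.pattern_counts < 0):
            raise ValueError("negative count")
        for j, t in enumerate(self.tests):
            codes = self.patterns[:, j]
            legal = t.legal_codes()
            bad = (codes < legal.start) | (codes >= legal.stop)
            if np.any(bad):
                raise ValueError(
                    f"test {t.name!r}: illegal code(s) "
                    f"{sorted(set(codes[bad].tolist()))} (legal: {list(legal)})"
                )
        sizes = self.study_sizes
        if np.any(sizes < 1):
            empty = [self.study_ids[i] for i in np.where(sizes < 1)[0]]
            raise ValueError(f"study with no individuals (N_s = 0): {empty}")
        # duplicate pattern rows within a study
        key = np.column_stack([self.pattern_study, self.patterns])
        uniq = np.unique(key, axis=0)
        if uniq.shape[0] != key.shape[0]:
            raise ValueError("duplicate pattern row within a study")

    # -- individual-level view ---------------------------------------------
    @property
    def responses(self) -> np.ndarray:
        """(N_total, T) array of individual responses, canonical order."""
        if self._responses is None:
            self._responses = np.repeat(
                self.patterns, self.pattern_counts, axis=0
            )
        return self._responses

    @property
    def response_study(self) -> np.ndarray:
        return np.repeat(self.pattern_study, self.pattern_counts)

    def study_responses(self, s: int) -> np.ndarray:
        mask = self.pattern_study == s
        return np.repeat(self.patterns[mask], self.pattern_counts[mask], axis=0)

    def cross_class_table(self, s: int) -> CrossClassTable:
        mask = self.pattern_study == s
        return CrossClassTable(
            study=self.study_ids[s],
            patterns=self.patterns[mask].copy(),
            counts=self.pattern_counts[mask].copy(),
        )

    def to_individual_frame(self) -> pd.DataFrame:
        """Canonical individual-level table (for audit export)."""
        df = pd.DataFrame(self.responses, columns=[t.name for t in self.tests])
        df.insert(0, "study", [self.study_ids[i] for i in self.response_study])
        return df

    def to_long_counts(self) -> pd.DataFrame:
        """Long-format counts table (the loader's input format)."""
        df = pd.DataFrame(self.patterns, columns=[t.name for t in self.tests])
        df.insert(0, "study", [self.study_ids[i] for i in self.pattern_study])
        df["count"] = self.pattern_counts
        return df


def _canonical_order(study_idx, patterns, counts):
    order = np.lexsort(tuple(patterns[:, j] for j in range(patterns.shape[1] - 1, -1, -1))
                       + (study_idx,))
    return study_idx[order], patterns[order], counts[order]


def dataset_from_patterns(tests, study_ids, study_idx, patterns, counts,
                          drop_zero=True) -> MetaDataset:
    """Assemble a MetaDataset from pattern arrays (canonicalised, validated)."""
    study_idx = np.asarray(study_idx, dtype=int)
    patterns = np.asarray(patterns, dtype=int)
    counts = np.asarray(counts, dtype=int)
    if drop_zero:
        keep = counts > 0
        # keep zero rows only long enough to detect duplicates
        dup_key = np.column_stack([study_idx, patterns])
        if np.unique(dup_key, axis=0).shape[0] != dup_key.shape[0]:
            raise ValueError("duplicate pattern row within a study")
        study_idx, patterns, counts = study_idx[keep], patterns[keep], counts[keep]
    study_idx, patterns, counts = _canonical_order(study_idx, patterns, counts)
    return MetaDataset(
        tests=list(tests),
        study_ids=list(study_ids),
        patterns=patterns,
        pattern_counts=counts,
        pattern_study=study_idx,
    )


def load_dataset(path, tests, label_maps=None) -> MetaDataset:
    """Read a long-format counts table into a MetaDataset.

    Parameters
    ----------
    path : str or file-like
        Delimited table with columns ``study``, one column per test name,
        and ``count``.  Separator is sniffed (',' or tab).
    tests : list of TestDefinition
        Panel definition; column order in the file need not match.
    label_maps : dict, optional
        Per-test ``{label: code}`` maps for non-integer categories
        (e.g. ``{"wells": {"L": 1, "M": 2, "H": 3}}``).  Supplied
        explicitly, never inferred.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["study"] + [t.name for t in tests] + ["count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    label_maps = label_maps or {}

    codes = np.empty((len(df), len(tests)), dtype=int)
    for j, t in enumerate(tests):
        col = df[t.name]
        if t.name in label_maps:
            mapping = label_maps[t.name]
            unknown = set(col.astype(str)) - set(map(str, mapping))
            if unknown:
                rows = df.index[~col.astype(str).isin(map(str, mapping))].tolist()
                raise ValueError(
                    f"test {t.name!r}: unknown category label(s) {sorted(unknown)} "
                    f"at row(s) {rows}"
                )
            codes[:, j] = col.astype(str).map(
                {str(k): v for k, v in mapping.items()}
            ).to_numpy()
        else:
            try:
                codes[:, j] = col.astype(int).to_numpy()
            except (ValueError, TypeError) as err:
                raise ValueError(
                    f"test {t.name!r}: categories not parseable as integers "
                    f"and no label map supplied"
                ) from err

    counts = df["count"].to_numpy()
    if np.any(counts < 0):
        rows = df.index[counts < 0].tolist()
        raise ValueError(f"negative count at row(s) {rows}")

    study_ids = list(pd.unique(df["study"]))
    study_idx = df["study"].map({sid: i for i, sid in enumerate(study_ids)}).to_numpy()

    # duplicate detection with row numbers, before dropping zeros
    key = pd.DataFrame(np.column_stack([study_idx, codes]))
    dup = key.duplicated(keep=False)
    if dup.any():
        raise ValueError(f"duplicate pattern row(s) at {df.index[dup].tolist()}")

    keep = counts > 0
    return dataset_from_patterns(
        tests, study_ids, study_idx[keep], codes[keep], counts[keep],
        drop_zero=False,
    )


def dichotomize(data: MetaDataset, test_index: int, cut_at: int) -> MetaDataset:
    """Collapse an ordinal test at cutpoint ``cut_at``: codes <= cut_at -> 0, > -> 1.

    For a three-category score, ``cut_at=2`` gives the "low + moderate versus
    high" coding and ``cut_at=1`` gives "low versus moderate + high".
    """
    t = data.tests[test_index]
    if not t.is_ordinal:
        raise ValueError(f"test {t.name!r} is already dichotomous")
    if not 1 <= cut_at <= t.n_cutpoints:
        raise ValueError(
            f"cut_at={cut_at} out of range 1..{t.n_cutpoints} for {t.name!r}"
        )
    patterns = data.patterns.copy()
    patterns[:, test_index] = (patterns[:, test_index] > cut_at).astype(int)
    tests = list(data.tests)
    tests[test_index] = replace(t, n_categories=2)
    # merged categories may collide: re-aggregate
    key = np.column_stack([data.pattern_study, patterns])
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    counts = np.zeros(len(uniq), dtype=int)
    np.add.at(counts, inv, data.pattern_counts)
    return dataset_from_patterns(
        tests, data.study_ids, uniq[:, 0], uniq[:, 1:], counts
    )


def observed_pairwise_correlations(data: MetaDataset):
    """Per-study Pearson correlations of the coded responses.

    Returns ``(corr, defined)``: ``corr`` is (S, T, T) with unit diagonal and
    ``np.nan`` where a test has zero within-study variance; ``defined`` is the
    matching boolean mask so undefined entries are flagged rather than
    silently propagated.
    """
    S, T = data.n_studies, data.n_tests
    corr = np.full((S, T, T), np.nan)
    defined = np.zeros((S, T, T), dtype=bool)
    for s in range(S):
        y = data.study_responses(s).astype(float)
        if y.shape[0] < 2:
            raise ValueError(f"study {data.study_ids[s]}: need N_s >= 2")
        sd = y.std(axis=0)
        ok = sd > 0
        corr[s][np.ix_(ok, ok)] = np.corrcoef(y[:, ok], rowvar=False).reshape(
            ok.sum(), ok.sum()
        )
        defined[s][np.ix_(ok, ok)] = True
        np.fill_diagonal(corr[s], 1.0)
        np.fill_diagonal(defined[s], True)
    return corr, defined
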