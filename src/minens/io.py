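"""Prediction tables and location-label mapping.

The central container is :class:`PredictionTable`: a rectangular matrix of
categorical subcellular-location labels, one row per protein and one column
per component predictor, optionally paired with a true-label column.
Component predictors use heterogeneous native vocabularies ("extra", "plas",
"golg", ...), so a :class:`LocationMapping` collapses them onto a small
unified vocabulary before any downstream scoring.

Tables are stored on disk as plain TSV (tab-delimited, UTF-8, header row,
no quoting) so that a write/read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel for a missing prediction. Rows containing it are excluded from
#: contribution scoring and feature selection.
NA_LABEL = "NA"

#: Default unified vocabulary: four main compartments plus a catch-all.
UNIFIED_5 = ("Cytosol", "Mitochondrion", "Nucleus", "Secretory", "Others")

#: High-resolution yeast vocabulary (secretory pathway split up).
UNIFIED_7 = (
    "Cytosol",
    "Mitochondrion",
    "Nucleus",
    "ER",
    "Vacuole",
    "Golgi",
    "Cell Periphery",
)

#: Compartment classes that collapse onto the unified Secretory label.
SECRETORY_CLASSES = (
    "extracellular",
    "plasma membrane",
    "endoplasmic reticulum",
    "golgi apparatus",
    "lysosomal",
    "vacuolar",
)

_GENERIC = "*"


class TableValidationError(ValueError):
    """A prediction table violates a structural invariant."""


@dataclass(frozen=True, eq=False)
class PredictionTable:
    """Protein x predictor matrix of categorical location labels.

    Parameters
    ----------
    protein_ids : list of str
        Unique row identifiers.
    predictor_names : list of str
        Unique column identifiers for the component predictors.
    predictions : ndarray of str, shape (n_proteins, n_predictors)
        Predicted location labels. Missing predictions must use the
        explicit sentinel ``"NA"``; empty strings are invalid.
    true_labels : list of str, optional
        Curated localization per protein; ``None`` for prediction-only
        tables.
    """

    protein_ids: list[str]
    predictor_names: list[str]
    predictions: np.ndarray
    true_labels: list[str] | None = None

    def __post_init__(self) -> None:
        preds = np.asarray(self.predictions, dtype=object)
        object.__setattr__(self, "predictions", preds)
        if preds.ndim != 2:
            raise TableValidationError("predictions must be a 2-D matrix")
        n, p = preds.shape
        if len(self.protein_ids) != n:
            raise TableValidationError(
                f"{len(self.protein_ids)} protein ids for {n} rows"
            )
        if len(self.predictor_names) != p:
            raise TableValidationError(
                f"{len(self.predictor_names)} predictor names for {p} columns"
            )
        if len(set(self.protein_ids)) != n:
            dupes = _duplicates(self.protein_ids)
            raise TableValidationError(f"duplicate protein id(s): {dupes}")
        if len(set(self.predictor_names)) != p:
            dupes = _duplicates(self.predictor_names)
            raise TableValidationError(f"duplicate predictor name(s): {dupes}")
        for j, name in enumerate(self.predictor_names):
            for i, pid in enumerate(self.protein_ids):
                cell = preds[i, j]
                if not isinstance(cell, str) or cell == "":
                    raise TableValidationError(
                        f"empty cell at row {pid!r}, column {name!r}"
                    )
        if self.true_labels is not None:
            if len(self.true_labels) != n:
                raise TableValidationError(
                    f"{len(self.true_labels)} true labels for {n} rows"
                )
            for i, lab in enumerate(self.true_labels):
                if not isinstance(lab, str) or lab == "":
                    raise TableValidationError(
                        f"empty true label at row {self.protein_ids[i]!r}"
                    )

    @property
    def n_proteins(self) -> int:
        return self.predictions.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.predictions.shape[1]

    @property
    def has_truth(self) -> bool:
        return self.true_labels is not None

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with no ``NA`` sentinel prediction."""
        return ~(self.predictions == NA_LABEL).any(axis=1)

    def subset_columns(self, indices) -> "PredictionTable":
        """A new table restricted to the given predictor columns."""
        idx = list(indices)
        return PredictionTable(
            protein_ids=list(self.protein_ids),
            predictor_names=[self.predictor_names[j] for j in idx],
            predictions=self.predictions[:, idx].copy(),
            true_labels=None if self.true_labels is None else list(self.true_labels),
        )

    def subset_rows(self, indices) -> "PredictionTable":
        idx = list(indices)
        return PredictionTable(
            protein_ids=[self.protein_ids[i] for i in idx],
            predictor_names=list(self.predictor_names),
            predictions=self.predictions[idx, :].copy(),
            true_labels=None
            if self.true_labels is None
            else [self.true_labels[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view: protein_id, optional true_label, predictor columns."""
        data: dict[str, list] = {"protein_id": list(self.protein_ids)}
        if self.true_labels is not None:
            data["true_label"] = list(self.true_labels)
        for j, name in enumerate(self.predictor_names):
            data[name] = list(self.predictions[:, j])
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionTable):
            return NotImplemented
        return (
            self.protein_ids == other.protein_ids
            and self.predictor_names == other.predictor_names
            and self.true_labels == other.true_labels
            and self.predictions.shape == other.predictions.shape
            and bool((self.predictions == other.predictions).all())
        )


def _duplicates(items) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


@dataclass(frozen=True)
class LocationMapping:
    """Per-predictor dictionary from native labels to unified locations.

    ``per_predictor`` maps a predictor name to its native-label dictionary;
    the special predictor key ``"*"`` holds generic entries consulted when a
    predictor-specific entry is absent. When ``others_fallback`` is true,
    any label still unmapped resolves to ``"Others"`` (the convention for
    the built-in 5-location scheme, where everything outside the four main
    compartments is *Others*).
    """

    per_predictor: dict[str, dict[str, str]]
    vocabulary: tuple[str, ...] = UNIFIED_5
    others_fallback: bool = False

    def __post_init__(self) -> None:
        for pred, entries in self.per_predictor.items():
            for native, unified in entries.items():
                if unified not in self.vocabulary:
                    raise ValueError(
                        f"mapping for predictor {pred!r} sends {native!r} to "
                        f"{unified!r}, which is outside the unified vocabulary"
                    )

    def lookup(self, predictor: str, native_label: str) -> str:
        """Unified label for a predictor's native label.

        Resolution order: predictor-specific entry, generic ``"*"`` entry,
        identity on labels already in the unified vocabulary, then the
        *Others* fallback if enabled.
        """
        label = native_label.strip()
        specific = self.per_predictor.get(predictor, {})
        if label in specific:
            return specific[label]
        generic = self.per_predictor.get(_GENERIC, {})
        if label in generic:
            return generic[label]
        if label in self.vocabulary:
            return label
        if self.others_fallback:
            return "Others"
        raise KeyError(
            f"no mapping for native label {label!r} of predictor {predictor!r}"
        )


def builtin_mappings(vocabulary: tuple[str, ...] = UNIFIED_5) -> LocationMapping:
    """The built-in mapping onto the 5 unified locations.

    Covers the documented CELLO and WoLFPSORT native vocabularies plus the
    generic six-class secretory rule (extracellular, plasma membrane, ER,
    Golgi apparatus, lysosomal and vacuolar compartments all collapse onto
    ``Secretory``); any other label outside the four main compartments
    resolves to ``Others``.
    """
    generic = {cls: "Secretory" for cls in SECRETORY_CLASSES}
    cello = {
        "extra": "Secretory",
        "plas": "Secretory",
        "er": "Secretory",
        "vacu": "Secretory",
        "golgi": "Secretory",
        "lyso": "Secretory",
        "chlo": "Others",
        "pero": "Others",
        "cytos": "Others",
    }
    wolfpsort = {
        "E.R.": "Secretory",
        "extr": "Secretory",
        "plas": "Secretory",
        "golg": "Secretory",
        "lyso": "Secretory",
        "vacu": "Secretory",
        "chlo": "Others",
        "cysk": "Others",
        "pero": "Others",
    }
    return LocationMapping(
        per_predictor={_GENERIC: generic, "CELLO": cello, "WoLFPSORT": wolfpsort},
        vocabulary=vocabulary,
        others_fallback=True,
    )


def map_locations(table: PredictionTable, mapping: LocationMapping) -> PredictionTable:
    """Replace every native label in the table by its unified location.

    The ``NA`` sentinel passes through unchanged. True labels, when present,
    are mapped with the generic rule (predictor key ``"*"``).

    Raises
    ------
    KeyError
        If a native label has no mapping entry for its predictor; the error
        names the predictor and the label.
    """
    mapped = np.empty_like(table.predictions)
    for j, name in enumerate(table.predictor_names):
        for i in range(table.n_proteins):
            cell = table.predictions[i, j]
            mapped[i, j] = cell if cell == NA_LABEL else mapping.lookup(name, cell)
    truth = table.true_labels
    if truth is not None:
        truth = [mapping.lookup(_GENERIC, t) for t in truth]
    return PredictionTable(
        protein_ids=list(table.protein_ids),
        predictor_names=list(table.predictor_names),
        predictions=mapped,
        true_labels=truth,
    )


def read_prediction_table(path, has_truth: bool = True) -> PredictionTable:
    """Read a TSV prediction table.

    Expected layout: header row with ``protein_id`` first, then
    ``true_label`` when ``has_truth``, then one column per predictor.
    Cells are whitespace-trimmed; empty cells, ragged rows and duplicate
    identifiers raise :class:`TableValidationError` naming the offender.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_filter=False,
        quoting=3,  # csv.QUOTE_NONE
        skip_blank_lines=True,
    )
    df.columns = [str(c).strip() for c in df.columns]
    if df.columns[0] != "protein_id":
        raise TableValidationError(
            f"first column must be 'protein_id', got {df.columns[0]!r}"
        )
    df = df.map(lambda s: s.strip())
    cols = list(df.columns)
    truth = None
    if has_truth:
        if "true_label" not in cols:
            raise TableValidationError("has_truth=True but no 'true_label' column")
        truth = df["true_label"].tolist()
    predictor_cols = [c for c in cols if c not in ("protein_id", "true_label")]
    if not predictor_cols:
        raise TableValidationError("no predictor columns found")
    return PredictionTable(
        protein_ids=df["protein_id"].tolist(),
        predictor_names=predictor_cols,
        predictions=df[predictor_cols].to_numpy(dtype=object),
        true_labels=truth,
    )


def write_prediction_table(table: PredictionTable, path) -> None:
    """Write a table as TSV so that :func:`read_prediction_table` inverts it."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_mapping(path, vocabulary: tuple[str, ...] = UNIFIED_5) -> LocationMapping:
    """Read a mapping TSV with columns predictor, native_label, unified_label.

    The predictor value ``"*"`` denotes the generic rule.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, quoting=3)
    required = {"predictor", "native_label", "unified_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping file must have columns {sorted(required)}")
    per: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        per.setdefault(row["predictor"].strip(), {})[row["native_label"].strip()] = (
            row["unified_label"].strip()
        )
    return LocationMapping(per_predictor=per, vocabulary=vocabulary)
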