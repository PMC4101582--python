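"""Sample-by-channel intensity panels and their delimited on-disk format.

A panel is stored sample-major: one row per spectrum, one column per m/z
channel.  On disk the format is plain delimited text with an m/z header
row, a leading ``sample_id`` column, and (optionally) a trailing ``label``
column.  Labels may alternatively live in a separate two-column file
mapping ``sample_id`` to a class code.

Channels are 0-based inside the library; user-facing reports give 1-based
channel indices alongside the m/z value, which is the biological
identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpectraMatrix",
    "SpectraFormatError",
    "read_matrix",
    "write_matrix",
]

#: decimal precision (significant digits) used by :func:`write_matrix`;
#: round-trips are exact to ~1e-12 relative for doubles of ordinary size.
WRITE_PRECISION = 12

ID_COLUMN = "sample_id"
LABEL_COLUMN = "label"


class SpectraFormatError(ValueError):
    """A delimited spectra file violates the format contract."""


@dataclass
class SpectraMatrix:
    """Intensity panel with an m/z axis and optional class labels.

    Parameters
    ----------
    intensities
        Real matrix, ``n_samples x n_channels`` (arbitrary intensity units).
    mz
        Strictly increasing vector of mass-to-charge values (Daltons),
        one per channel.
    sample_ids
        Unique string identifier per sample.
    labels
        Optional class code per sample.  When present there must be at
        least two samples and at least two distinct classes.
    """

    intensities: np.ndarray
    mz: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.intensities.ndim != 2:
            raise SpectraFormatError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if self.mz.shape != (p,):
            raise SpectraFormatError(
                f"mz length {self.mz.shape} does not match {p} channels"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("intensities contain NaN/inf entries")
        if not np.all(np.diff(self.mz) > 0):
            raise SpectraFormatError("m/z values must be strictly increasing")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise SpectraFormatError("sample_ids length does not match rows")
        if len(set(self.sample_ids)) != n:
            raise SpectraFormatError("sample_ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise SpectraFormatError("labels length does not match rows")
            if n < 2:
                raise SpectraFormatError("labelled panels need >= 2 samples")
            if len(set(self.labels.tolist())) < 2:
                raise SpectraFormatError("labels must contain >= 2 classes")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> list:
        if self.labels is None:
            return []
        return sorted(set(self.labels.tolist()))

    def with_intensities(self, intensities: np.ndarray) -> "SpectraMatrix":
        """Copy of this panel with the intensity matrix replaced."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


def _fmt(x: float) -> str:
    return f"{x:.{WRITE_PRECISION}g}"


def read_matrix(path, labels_path=None, delimiter: str = ",") -> SpectraMatrix:
    """Read a delimited intensity panel.

    The first row holds the m/z values (with an optional leading
    ``sample_id`` header cell and optional trailing ``label`` cell); each
    subsequent row is a sample id followed by one intensity per channel.
    ``labels_path``, if given, is a two-column file mapping sample id to
    class code and overrides any in-file label column.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SpectraFormatError(f"{path}: empty file")

    header = lines[0].split(delimiter)
    start = 0
    if header and header[0].strip() == ID_COLUMN:
        start = 1
    has_label_col = bool(header) and header[-1].strip() == LABEL_COLUMN
    end = len(header) - 1 if has_label_col else len(header)
    try:
        mz = np.array([float(v) for v in header[start:end]])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric m/z header: {exc}") from None
    n_channels = mz.size

    ids: list[str] = []
    rows: list[list[float]] = []
    file_labels: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(delimiter)
        expected = 1 + n_channels + (1 if has_label_col else 0)
        if len(fields) != expected:
            raise SpectraFormatError(
                f"{path}:{lineno}: expected {expected} fields, got {len(fields)}"
            )
        ids.append(fields[0].strip())
        body = fields[1 : 1 + n_channels]
        try:
            rows.append([float(v) for v in body])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}:{lineno}: {exc}") from None
        if has_label_col:
            file_labels.append(fields[-1].strip())

    labels: np.ndarray | None = np.array(file_labels) if has_label_col else None
    if labels_path is not None:
        mapping: dict[str, str] = {}
        with open(labels_path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = line.split(delimiter)
                if len(parts) != 2:
                    raise SpectraFormatError(
                        f"{labels_path}: expected 2 columns, got {len(parts)}"
                    )
                mapping[parts[0].strip()] = parts[1].strip()
        # a header row like "sample_id,label" is tolerated
        mapping.pop(ID_COLUMN, None)
        missing = [s for s in ids if s not in mapping]
        if missing:
            raise KeyError(f"{labels_path}: no label for sample id(s) {missing}")
        labels = np.array([mapping[s] for s in ids])

    return SpectraMatrix(np.array(rows), mz, ids, labels)


def write_matrix(spectra: SpectraMatrix, path, delimiter: str = ","):
    """Write a panel in the format accepted by :func:`read_matrix`.

    Values are written with :data:`WRITE_PRECISION` significant digits, so
    ``read_matrix(write_matrix(x))`` reproduces ``x`` to that precision and
    a second write is byte-identical to the first.
    """
    header = [ID_COLUMN] + [_fmt(v) for v in spectra.mz]
    if spectra.labels is not None:
        header.append(LABEL_COLUMN)
    out_lines = [delimiter.join(header)]
    for i, sid in enumerate(spectra.sample_ids):
        row = [sid] + [_fmt(v) for v in spectra.intensities[i]]
        if spectra.labels is not None:
            row.append(str(spectra.labels[i]))
        out_lines.append(delimiter.join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out_lines) + "\n")
    return path
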