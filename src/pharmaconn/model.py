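"""Shared data model for the connectivity pipeline.

The pipeline operates on a geometry-free brain model: a set of G
"grayordinates" (cortical surface vertices or subcortical gray-matter
voxels in the real acquisition; abstract indexed units here) carrying
structure, functional-network and parcel labels plus a neighborhood
graph, and per-run BOLD time-series matrices with motion and nuisance
channels.  No surface geometry, registration or resampling is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRUCTURES = (
    "cortex-L",
    "cortex-R",
    "thalamus",
    "amygdala",
    "other-subcortex",
    "ventricle-proxy",
    "wm-proxy",
)

NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "frontoparietal",
    "default",
)
NETWORK_NONE = "none"

#: sensory-somatomotor vs associative split used throughout
SENSORY_NETWORKS = ("visual", "somatomotor")
ASSOCIATIVE_NETWORKS = (
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "frontoparietal",
    "default",
)

CONDITIONS = ("Pla", "LSD", "KetLSD")

MAP_KINDS = (
    "gbc_r_fz",
    "gbc_cov",
    "seed_r_fz",
    "seed_cov",
    "gs_beta",
    "local_var",
    "z",
    "expression_parcel",
)


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """A container file is structurally malformed."""


@dataclass
class GrayordinateSpace:
    """Labels and adjacency for a set of grayordinates.

    Parameters
    ----------
    structure : array of str, length G
        One of :data:`STRUCTURES` per grayordinate.
    network : array of str, length G
        Functional network label; ``"none"`` outside cortex.
    parcel : int array, length G
        Parcel index in ``0..P-1`` for cortical grayordinates, ``-1``
        elsewhere.
    edges : (E, 2) int array
        Undirected adjacency as an edge list (each pair stored once).
    """

    structure: np.ndarray
    network: np.ndarray
    parcel: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.structure = np.asarray(self.structure, dtype=object)
        self.network = np.asarray(self.network, dtype=object)
        self.parcel = np.asarray(self.parcel, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.validate()

    # -- derived masks -------------------------------------------------
    @property
    def n_gray(self) -> int:
        return self.structure.size

    @property
    def n_parcels(self) -> int:
        return int(self.parcel.max()) + 1 if (self.parcel >= 0).any() else 0

    def structure_mask(self, *names: str) -> np.ndarray:
        return np.isin(self.structure, names)

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.structure_mask("cortex-L", "cortex-R")

    @property
    def gray_mask(self) -> np.ndarray:
        """Gray matter = cortex plus labeled subcortex (no vent/WM proxies)."""
        return self.structure_mask(
            "cortex-L", "cortex-R", "thalamus", "amygdala", "other-subcortex"
        )

    @property
    def thalamus_mask(self) -> np.ndarray:
        return self.structure_mask("thalamus")

    def network_mask(self, name: str) -> np.ndarray:
        return self.network == name

    def validate(self) -> None:
        g = self.n_gray
        if self.network.size != g or self.parcel.size != g:
            raise ValidationError("structure/network/parcel length mismatch")
        bad = ~np.isin(self.structure, STRUCTURES)
        if bad.any():
            raise ValidationError(
                f"unknown structure labels: {set(self.structure[bad])}"
            )
        bad = ~np.isin(self.network, NETWORKS + (NETWORK_NONE,))
        if bad.any():
            raise ValidationError(f"unknown network labels: {set(self.network[bad])}")
        cortex = self.cortex_mask
        if (self.network[cortex] == NETWORK_NONE).any():
            raise ValidationError("cortical grayordinate without network label")
        if (self.parcel[cortex] < 0).any():
            raise ValidationError("cortical grayordinate without parcel label")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= g:
                raise ValidationError("edge endpoint out of range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValidationError("adjacency contains a self-loop")
            # symmetric by construction (edge list, each undirected pair once);
            # reject duplicates in either orientation
            canon = np.sort(self.edges, axis=1)
            uniq = np.unique(canon, axis=0)
            if uniq.shape[0] != canon.shape[0]:
                raise ValidationError("duplicate edges in adjacency")


@dataclass
class BoldRun:
    """One subject x condition x session BOLD acquisition.

    ``bold`` is T x G in arbitrary BOLD units; ``motion`` is T x 6
    (3 translations in mm, 3 rotations in radians); ``ventricle_ts`` and
    ``wm_ts`` are precomputed length-T nuisance channels.
    """

    subject: str
    condition: str
    session: int
    bold: np.ndarray
    tr: float
    motion: np.ndarray
    ventricle_ts: np.ndarray
    wm_ts: np.ndarray

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=np.float64)
        self.motion = np.asarray(self.motion, dtype=np.float64)
        self.ventricle_ts = np.asarray(self.ventricle_ts, dtype=np.float64)
        self.wm_ts = np.asarray(self.wm_ts, dtype=np.float64)
        self.validate()

    @property
    def run_id(self) -> str:
        return f"{self.subject}_{self.condition}_s{self.session}"

    @property
    def n_frames(self) -> int:
        return self.bold.shape[0]

    @property
    def n_gray(self) -> int:
        return self.bold.shape[1]

    def validate(self) -> None:
        rid = f"{self.subject}_{self.condition}_s{self.session}"
        if self.condition not in CONDITIONS:
            raise ValidationError(f"run {rid}: unknown condition {self.condition!r}")
        if self.session not in (1, 2):
            raise ValidationError(f"run {rid}: session must be 1 or 2")
        if self.bold.ndim != 2 or self.bold.shape[0] < 8:
            raise ValidationError(f"run {rid}: bold must be TxG with T >= 8")
        t = self.bold.shape[0]
        if self.motion.shape != (t, 6):
            raise ValidationError(f"run {rid}: motion shape {self.motion.shape} != ({t}, 6)")
        if self.ventricle_ts.shape != (t,) or self.wm_ts.shape != (t,):
            raise ValidationError(f"run {rid}: nuisance channel length != T={t}")
        if not self.tr > 0:
            raise ValidationError(f"run {rid}: tr must be positive")
        for name, arr in (
            ("bold", self.bold),
            ("motion", self.motion),
            ("ventricle_ts", self.ventricle_ts),
            ("wm_ts", self.wm_ts),
        ):
            if not np.isfinite(arr).all():
                raise ValidationError(f"run {rid}: non-finite values in {name}")

    def with_bold(self, bold: np.ndarray) -> "BoldRun":
        """Copy of this run with the BOLD matrix replaced."""
        return BoldRun(
            subject=self.subject,
            condition=self.condition,
            session=self.session,
            bold=bold,
            tr=self.tr,
            motion=self.motion,
            ventricle_ts=self.ventricle_ts,
            wm_ts=self.wm_ts,
        )


@dataclass
class ScalarMap:
    """One value per grayordinate (or per parcel for parcel-level maps)."""

    values: np.ndarray
    kind: str
    space_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in MAP_KINDS:
            raise ValidationError(f"unknown map kind {self.kind!r}")
        if self.values.ndim != 1:
            raise ValidationError("ScalarMap values must be 1-D")


@dataclass
class CohortDesign:
    """Run roster: (subject, condition, session) -> run id, plus exclusions."""

    table: pd.DataFrame  # columns: subject, condition, session, run_id
    excluded: dict = field(default_factory=dict)  # subject -> reason

    def __post_init__(self) -> None:
        required = {"subject", "condition", "session", "run_id"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"design table must have columns {sorted(required)}")

    @property
    def subjects(self) -> list:
        return sorted(self.table["subject"].unique())

    @property
    def included_subjects(self) -> list:
        return [s for s in self.subjects if s not in self.excluded]

    def run_id(self, subject: str, condition: str, session: int) -> str:
        t = self.table
        row = t[
            (t.subject == subject) & (t.condition == condition) & (t.session == session)
        ]
        if len(row) != 1:
            raise ValidationError(
                f"missing cell for subject {subject}, condition {condition}, "
                f"session {session}"
            )
        return row["run_id"].iloc[0]

    def validate_full_crossing(self, sessions=(1, 2)) -> None:
        for s in self.included_subjects:
            for c in CONDITIONS:
                for e in sessions:
                    self.run_id(s, c, e)


@dataclass
class ExpressionMatrix:
    """Gene x parcel cortical expression, z-scored within gene across parcels."""

    genes: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.genes) != self.values.shape[0]:
            raise ValidationError("gene list length != expression rows")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols must be unique")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]
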