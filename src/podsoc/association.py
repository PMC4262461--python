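"""Half-weight association indices and dyad classification.

The half-weight index (HWI) for a dyad (A, B) is ``2N / (N_A + N_B)`` where
``N`` is the number of group sightings containing both animals and ``N_A``,
``N_B`` are each animal's total group sightings.  It ranges from 0 (never
seen together) to 1 (always in the same group) and corrects for the bias of
scoring animals more readily apart than together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sightings import GroupByIndividual

__all__ = [
    "AssociationMatrix",
    "DyadClassification",
    "hwi_matrix",
    "hwi_from_matrix",
    "individual_summary",
    "classify_dyads",
    "write_matrix",
    "write_edgelist",
]

#: HWI class bins as closed/open intervals: low < 0.3, moderate in [0.3, 0.5],
#: high > 0.5 (both boundaries belong to "moderate").
CLASS_BINS = (("low", 0.0, 0.3), ("moderate", 0.3, 0.5), ("high", 0.5, 1.0))


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric HWI matrix together with the counts that generated it.

    Attributes
    ----------
    individuals : tuple of str
        Ordered labels; defines row/column order of all matrices.
    hwi : ndarray
        Symmetric half-weight indices; the diagonal is NaN, as are dyads
        whose combined sighting count is zero (masked).
    x : ndarray
        Symmetric counts of joint sightings per dyad.
    d : ndarray
        Per-individual total group sightings.
    attributes : pandas.DataFrame or None
        Per-individual sex / age_class, indexed by individual.
    """

    individuals: tuple[str, ...]
    hwi: np.ndarray
    x: np.ndarray
    d: np.ndarray
    attributes: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.individuals)

    def offdiag_values(self) -> np.ndarray:
        """Unordered off-diagonal HWIs (each dyad once), masked dyads dropped."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.hwi[iu]
        return vals[~np.isnan(vals)]

    def dyad_index(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n, k=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.hwi, index=list(self.individuals), columns=list(self.individuals)
        )


def hwi_from_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HWI, joint counts and totals from a binary GBI matrix.

    Returns ``(hwi, x, d)``; vectorised as ``x = G'G`` with
    ``hwi_ij = 2 x_ij / (d_i + d_j)``.  Dyads with ``d_i + d_j = 0`` and the
    diagonal are NaN.
    """
    g = np.asarray(matrix, dtype=np.float64)
    x = g.T @ g
    d = np.diag(x).copy()
    denom = d[:, None] + d[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, 2.0 * x / denom, np.nan)
    np.fill_diagonal(hwi, np.nan)
    np.fill_diagonal(x, 0)
    return hwi, x, d


def hwi_matrix(gbi: GroupByIndividual) -> AssociationMatrix:
    """Compute the half-weight association matrix from a GBI matrix."""
    hwi, x, d = hwi_from_matrix(gbi.matrix)
    return AssociationMatrix(
        individuals=gbi.individuals,
        hwi=hwi,
        x=x,
        d=d,
        attributes=gbi.column_attributes,
    )


def _sex_pair_label(s1: str, s2: str) -> str:
    if "UN" in (s1, s2):
        return "unknown_pairing"
    key = "".join(sorted((s1, s2)))
    return {"FF": "female-female", "FM": "female-male", "MM": "male-male"}[key]


def individual_summary(am: AssociationMatrix) -> pd.DataFrame:
    """Mean / max / min HWI per individual plus per-sex-pairing dyad summaries.

    Returns a per-individual frame; the per-pairing aggregate (dyad counts and
    means for female-female, male-male, female-male and pairings involving
    unknown sex) is attached as ``frame.attrs['sex_pairings']``.
    """
    rows = []
    for i, ind in enumerate(am.individuals):
        vals = np.delete(am.hwi[i], i)
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "individual_id": ind,
                "mean_hwi": float(np.mean(vals)) if vals.size else np.nan,
                "max_hwi": float(np.max(vals)) if vals.size else np.nan,
                "min_hwi": float(np.min(vals)) if vals.size else np.nan,
                "n_sightings": int(am.d[i]),
            }
        )
    frame = pd.DataFrame(rows).set_index("individual_id")

    if am.attributes is not None:
        sex = am.attributes["sex"].reindex(list(am.individuals)).to_numpy()
        iu, ju = am.dyad_index()
        labels = np.array([_sex_pair_label(sex[i], sex[j]) for i, j in zip(iu, ju)])
        vals = am.hwi[iu, ju]
        agg = []
        for lab in ("female-female", "male-male", "female-male", "unknown_pairing"):
            sel = vals[(labels == lab) & ~np.isnan(vals)]
            n_dyads = int((labels == lab).sum())
            agg.append(
                {
                    "pairing": lab,
                    "n_dyads": n_dyads,
                    "mean_hwi": float(sel.mean()) if sel.size else np.nan,
                    "sd_hwi": float(sel.std(ddof=1)) if sel.size > 1 else np.nan,
                    "max_hwi": float(sel.max()) if sel.size else np.nan,
                }
            )
        frame.attrs["sex_pairings"] = pd.DataFrame(agg).set_index("pairing")
    return frame


def hwi_class(value: float) -> str:
    """Class bin of an HWI value: low (<0.3), moderate (0.3-0.5), high (>0.5)."""
    if value < CLASS_BINS[1][1]:
        return "low"
    if value <= CLASS_BINS[1][2]:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class DyadClassification:
    """Preferred / avoided / neutral labels per dyad.

    A dyad is *preferred* when its HWI is at least twice the population mean
    index (zeros included), and *avoided* when its HWI is exactly zero.
    ``dyads`` has one row per unordered off-diagonal dyad.  Because the
    literature is inconsistent about the dyad universe, ``dyad_counts``
    reports the number of dyads under all three conventions (unordered,
    ordered non-self, ordered with self) so any published total can be
    compared.
    """

    threshold: float
    mean_hwi: float
    dyads: pd.DataFrame
    per_individual: pd.DataFrame
    dyad_counts: dict


def classify_dyads(am: AssociationMatrix) -> DyadClassification:
    iu, ju = am.dyad_index()
    vals = am.hwi[iu, ju]
    ok = ~np.isnan(vals)
    mean = float(vals[ok].mean())
    threshold = 2.0 * mean

    rows = []
    for i, j, v in zip(iu[ok], ju[ok], vals[ok]):
        label = "preferred" if v >= threshold else ("avoided" if v == 0.0 else "neutral")
        rows.append(
            {
                "individual_1": am.individuals[i],
                "individual_2": am.individuals[j],
                "hwi": float(v),
                "label": label,
                "class_bin": hwi_class(float(v)),
            }
        )
    dyads = pd.DataFrame(rows)

    per_ind = []
    for ind in am.individuals:
        sub = dyads[(dyads["individual_1"] == ind) | (dyads["individual_2"] == ind)]
        per_ind.append(
            {
                "individual_id": ind,
                "n_preferred": int((sub["label"] == "preferred").sum()),
                "n_avoided": int((sub["label"] == "avoided").sum()),
                "n_associates": int((sub["hwi"] > 0).sum()),
            }
        )
    n = am.n
    n_unordered = int(ok.sum())
    counts = {
        "unordered": n_unordered,
        "ordered": 2 * n_unordered,
        "ordered_with_self": 2 * n_unordered + n,
    }
    return DyadClassification(
        threshold=threshold,
        mean_hwi=mean,
        dyads=dyads,
        per_individual=pd.DataFrame(per_ind).set_index("individual_id"),
        dyad_counts=counts,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(am: AssociationMatrix, path, sep: str = ",") -> None:
    """Labelled dense HWI matrix as delimited text."""
    am.to_frame().to_csv(path, sep=sep)


def write_edgelist(
    am: AssociationMatrix, path, min_hwi: float = 0.0, sep: str = ","
) -> None:
    """Edge list (i, j, hwi, x_ij), optionally thresholded for sociograms.

    A ``min_hwi`` of e.g. 0.30 reproduces the conventional sociogram cut that
    displays only moderate-and-above associations.
    """
    iu, ju = am.dyad_index()
    rows = []
    for i, j in zip(iu, ju):
        v = am.hwi[i, j]
        if np.isnan(v) or v < min_hwi:
            continue
        rows.append(
            (am.individuals[i], am.individuals[j], float(v), int(am.x[i, j]))
        )
    pd.DataFrame(rows, columns=["individual_1", "individual_2", "hwi", "n_together"]).to_csv(
        path, sep=sep, index=False
    )
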