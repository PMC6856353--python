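"""Twin-cohort containers.

A cohort holds paired observations on MZ (monozygotic) and DZ (dizygotic)
twins.  Internally the data live in a dense ``(n_pairs, 2, p)`` array with
``NaN`` marking missing entries; a singleton is a pair whose second twin is
entirely missing.  The stacked per-pair observation vector used by the
likelihood is ``[twin1 variables..., twin2 variables...]`` (length ``2p``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Expected cross-twin correlation of additive-genetic factors by zygosity:
#: MZ twins share all segregating genes, DZ twins on average half.
GENETIC_CROSS_TWIN_FACTOR = {"MZ": 1.0, "DZ": 0.5}


def zygosity_factor(label: str) -> float:
    """Cross-twin additive-genetic correlation for a zygosity label."""
    try:
        return GENETIC_CROSS_TWIN_FACTOR[label]
    except KeyError:
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {label!r}") from None


@dataclass
class TwinPair:
    """One family: two (possibly incomplete) observation vectors."""

    family_id: object
    zygosity: str
    twin1: np.ndarray
    twin2: np.ndarray | None = None

    def __post_init__(self) -> None:
        zygosity_factor(self.zygosity)
        self.twin1 = np.asarray(self.twin1, dtype=float)
        if self.twin2 is None:
            self.twin2 = np.full_like(self.twin1, np.nan)
        else:
            self.twin2 = np.asarray(self.twin2, dtype=float)
        if self.twin1.shape != self.twin2.shape:
            raise ValueError("twin1 and twin2 must have the same length")
        if not (np.isfinite(self.twin1).any() or np.isfinite(self.twin2).any()):
            raise ValueError("a twin pair must have at least one observed value")


@dataclass
class TwinCohort:
    """Paired MZ/DZ observations with possibly missing co-twins.

    Attributes
    ----------
    values : ndarray of shape (n_pairs, 2, p)
        Observations; NaN marks missing entries.
    zygosity : ndarray of shape (n_pairs,)
        ``"MZ"`` or ``"DZ"`` per family.
    variable_names : list of str
        Names of the p phenotypes, identical order for both twins.
    family_ids : ndarray of shape (n_pairs,)
    """

    values: np.ndarray
    zygosity: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    family_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must have shape (n_pairs, 2, p)")
        self.zygosity = np.asarray(self.zygosity, dtype=object)
        if self.zygosity.shape[0] != self.values.shape[0]:
            raise ValueError("zygosity length must match number of pairs")
        for z in np.unique(self.zygosity):
            zygosity_factor(z)
        if not self.variable_names:
            self.variable_names = [f"var{i + 1}" for i in range(self.n_variables)]
        if len(self.variable_names) != self.n_variables:
            raise ValueError("variable_names length must equal p")
        if self.family_ids is None:
            self.family_ids = np.arange(self.n_pairs)
        else:
            self.family_ids = np.asarray(self.family_ids)
        ok = np.isfinite(self.values).any(axis=(1, 2))
        if not ok.all():
            raise ValueError("every pair must have at least one observed value")

    # -- basic shape -------------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[2]

    @property
    def n_mz(self) -> int:
        return int(np.sum(self.zygosity == "MZ"))

    @property
    def n_dz(self) -> int:
        return int(np.sum(self.zygosity == "DZ"))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: list[TwinPair], variable_names=None) -> "TwinCohort":
        p = pairs[0].twin1.shape[0]
        values = np.full((len(pairs), 2, p), np.nan)
        zyg = np.empty(len(pairs), dtype=object)
        fam = np.empty(len(pairs), dtype=object)
        for i, pr in enumerate(pairs):
            values[i, 0] = pr.twin1
            values[i, 1] = pr.twin2
            zyg[i] = pr.zygosity
            fam[i] = pr.family_id
        return cls(values, zyg, list(variable_names or []), fam)

    @classmethod
    def from_table(cls, table: pd.DataFrame, variables: list[str]) -> "TwinCohort":
        """Build a cohort from a long-format phenotype table.

        ``table`` needs columns ``family_id``, ``twin`` (1 or 2), ``zygosity``
        plus one column per phenotype in ``variables``.  Zygosity must be
        constant within family and families hold at most two rows.
        """
        required = {"family_id", "twin", "zygosity"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
        fam_ids = []
        rows = []
        zygs = []
        for fid, grp in table.groupby("family_id", sort=False):
            if len(grp) > 2:
                raise ValueError(f"family {fid!r} has more than two individuals")
            if grp["zygosity"].nunique() > 1:
                raise ValueError(f"family {fid!r} has inconsistent zygosity")
            block = np.full((2, len(variables)), np.nan)
            for _, r in grp.iterrows():
                t = int(r["twin"])
                if t not in (1, 2):
                    raise ValueError("twin column must be 1 or 2")
                block[t - 1] = [r[v] for v in variables]
            fam_ids.append(fid)
            rows.append(block)
            zygs.append(grp["zygosity"].iloc[0])
        return cls(
            np.stack(rows), np.array(zygs, dtype=object), list(variables),
            np.array(fam_ids, dtype=object),
        )

    def to_table(self) -> pd.DataFrame:
        """Long-format table (one row per individual with any observed value)."""
        recs = []
        for i in range(self.n_pairs):
            for t in range(2):
                if np.isfinite(self.values[i, t]).any():
                    rec = {
                        "family_id": self.family_ids[i],
                        "twin": t + 1,
                        "zygosity": self.zygosity[i],
                    }
                    rec.update(dict(zip(self.variable_names, self.values[i, t])))
                    recs.append(rec)
        return pd.DataFrame(recs)

    # -- views -------------------------------------------------------------
    def stacked(self) -> np.ndarray:
        """Per-pair observation vectors, shape (n_pairs, 2p)."""
        return self.values.reshape(self.n_pairs, -1)

    def select_variables(self, idx) -> "TwinCohort":
        idx = list(idx)
        return TwinCohort(
            self.values[:, :, idx],
            self.zygosity,
            [self.variable_names[i] for i in idx],
            self.family_ids,
        )

    def subset(self, mask) -> "TwinCohort":
        mask = np.asarray(mask)
        return TwinCohort(
            self.values[mask], self.zygosity[mask], list(self.variable_names),
            self.family_ids[mask],
        )
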