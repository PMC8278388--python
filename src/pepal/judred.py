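"""Low-resolution "Judred" descriptors: 10 features by pure table lookup.

Every descriptor is computable from the one-letter code alone via a packaged
per-residue property table — no molecular-structure objects — which is what
makes whole-space pre-screening of 1e7+ peptide spaces tractable.

The 10 components and the interaction each proxies:

==========  =========================================  =====================
name        definition                                 physical mechanism
==========  =========================================  =====================
SP2         sp2 carbon count                           entropic loss
NH2         side-chain NH2/NH3 group count             hydrogen bonding
MW          molecular weight (g/mol)                   size
S           sulfur atom count                          hydrogen bonding
logP_WW     Wimley-White log P (positive=hydrophobic)  solubility
Z           net side-chain charge at pH 7              electrostatics
RotRatio    sp2/sp3 carbon ratio                       relative entropic loss
MaxASA      max solvent-accessible surface area (A^2)  hydrophobic effect
Bulkiness   summed Zimmerman bulkiness                 size
OH          side-chain hydroxyl count                  hydrogen bonding
==========  =========================================  =====================

Counting conventions (carried entirely by the table, so alternatives are a
one-file change): sp2 counts include one backbone carbonyl carbon per
residue; the sp3 denominator of RotRatio includes the backbone alpha carbon,
so it is >= 1 per residue and the ratio is always finite (polyglycine
included).  Peptides are linear zwitterions; the terminal NH3+/COO- cancel,
so Z is side-chain-only.  MW uses average free-amino-acid masses minus one
condensation water (18.015 g/mol) per peptide bond.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .peptides import ALPHABET, validate_peptide

#: Field names of the Judred vector, in canonical (export) order.
JUDRED_FIELDS = (
    "SP2",
    "NH2",
    "MW",
    "S",
    "logP_WW",
    "Z",
    "RotRatio",
    "MaxASA",
    "Bulkiness",
    "OH",
)

WATER_MASS = 18.015  # g/mol lost per peptide bond


def load_residue_table() -> pd.DataFrame:
    """Load the packaged per-residue property table (20 rows, read-only).

    Columns: mass_free_aa, ww_logp, sp2_carbons, sp3_carbons, nh2_groups,
    oh_groups, s_atoms, side_chain_charge, max_asa, bulkiness; indexed by
    one-letter residue code.  Value provenance is documented in the CSV
    header comments.
    """
    ref = importlib.resources.files("pepal.data").joinpath("residue_properties.csv")
    with ref.open() as fh:
        table = pd.read_csv(fh, comment="#", index_col="residue")
    missing = set(ALPHABET) - set(table.index)
    if missing or len(table) != 20:
        raise ValueError(f"residue table malformed: {len(table)} rows, missing {missing}")
    if table.isna().any().any():
        raise ValueError("residue table contains missing values")
    return table


class JudredCalculator:
    """Vectorised Judred descriptor generator over a residue property table.

    Per-residue columns are pre-extracted into arrays indexed by residue
    ordinal so that descriptor generation is pure integer indexing plus sums
    — throughput is what makes the first screening step usable on spaces
    that can never be materialised as structures.
    """

    def __init__(self, table: pd.DataFrame | None = None):
        self.table = table if table is not None else load_residue_table()
        order = list(ALPHABET)
        t = self.table.loc[order]
        self._codes = {aa: i for i, aa in enumerate(order)}
        self._mass = t["mass_free_aa"].to_numpy(float)
        self._ww = t["ww_logp"].to_numpy(float)
        self._sp2 = t["sp2_carbons"].to_numpy(float)
        self._sp3 = t["sp3_carbons"].to_numpy(float)
        self._nh2 = t["nh2_groups"].to_numpy(float)
        self._oh = t["oh_groups"].to_numpy(float)
        self._s = t["s_atoms"].to_numpy(float)
        self._z = t["side_chain_charge"].to_numpy(float)
        self._asa = t["max_asa"].to_numpy(float)
        self._bulk = t["bulkiness"].to_numpy(float)

    def _encode(self, peptide: str) -> np.ndarray:
        seq = validate_peptide(peptide)
        try:
            return np.fromiter((self._codes[aa] for aa in seq), dtype=np.intp, count=len(seq))
        except KeyError as exc:  # pragma: no cover - validate_peptide guards this
            raise KeyError(f"residue {exc} missing from property table") from None

    def vector(self, peptide: str) -> np.ndarray:
        """Judred vector for one peptide, ordered as :data:`JUDRED_FIELDS`."""
        idx = self._encode(peptide)
        n = len(idx)
        sp2 = self._sp2[idx].sum()
        sp3 = self._sp3[idx].sum()  # >= 1 per residue by table construction
        return np.array(
            [
                sp2,
                self._nh2[idx].sum(),
                self._mass[idx].sum() - (n - 1) * WATER_MASS,
                self._s[idx].sum(),
                self._ww[idx].sum(),
                self._z[idx].sum(),
                sp2 / sp3,
                self._asa[idx].sum(),
                self._bulk[idx].sum(),
                self._oh[idx].sum(),
            ]
        )

    def as_dict(self, peptide: str) -> dict[str, float]:
        """Named Judred values; the descriptor supplier for restriction filters."""
        return dict(zip(JUDRED_FIELDS, self.vector(peptide)))

    def matrix(self, peptides: Iterable[str]) -> np.ndarray:
        """Stacked Judred vectors, rows in input order."""
        rows = [self.vector(p) for p in peptides]
        return np.vstack(rows) if rows else np.empty((0, len(JUDRED_FIELDS)))

    def logp_ww(self, peptide: str) -> float:
        """Wimley-White peptide log P: sum of per-residue contributions.

        Positive values mean hydrophobic (poorly water-soluble); the standard
        solubility curation removes peptides with log P > 0.
        """
        return float(self._ww[self._encode(peptide)].sum())

    def net_charge(self, peptide: str) -> int:
        """Net side-chain charge at pH 7 (K/R = +1, D/E = -1, H = 0)."""
        return int(round(self._z[self._encode(peptide)].sum()))


def judred_vector(peptide: str, table: pd.DataFrame | None = None) -> np.ndarray:
    """One-shot convenience wrapper around :meth:`JudredCalculator.vector`."""
    return JudredCalculator(table).vector(peptide)


def batch_judred(
    peptides: Iterable[str], calculator: JudredCalculator | None = None
) -> Iterator[tuple[str, np.ndarray]]:
    """Stream ``(peptide, vector)`` pairs in input order, constant memory.

    Per-item errors propagate with the offending sequence named.
    """
    calc = calculator or JudredCalculator()
    for pep in peptides:
        try:
            yield pep, calc.vector(pep)
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"judred failed for {pep!r}: {exc}") from exc


def descriptors_frame(
    peptides: Iterable[str], calculator: JudredCalculator | None = None
) -> pd.DataFrame:
    """Judred descriptors as a DataFrame (column ``sequence`` + 10 features)."""
    calc = calculator or JudredCalculator()
    peps = list(peptides)
    df = pd.DataFrame(calc.matrix(peps), columns=list(JUDRED_FIELDS))
    df.insert(0, "sequence", peps)
    return df
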