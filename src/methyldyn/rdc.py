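"""Residual dipolar couplings: aligned-minus-isotropic differences and
linear (order-matrix / SVD) alignment-tensor fitting against candidate
structures, used to score which conformation matches the data.

The observed RDC of bond vector u is D = u^T S u with S the symmetric,
traceless Saupe order matrix scaled into Hz (the dipolar prefactor is
absorbed into S, which is the convention of direct linear fits).  Five
independent elements are solved by least squares from >= 5 bond vectors;
agreement is reported as the Pearson correlation and the Q-factor
rms(D_obs - D_calc)/rms(D_obs).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd


class DegenerateGeometryError(ValueError):
    pass


def rdc_from_couplings(
    aligned: pd.DataFrame, isotropic: pd.DataFrame
) -> pd.DataFrame:
    """RDC = (J + RDC) - J per residue from matched aligned/isotropic
    coupling tables (columns residue_id, J_Hz, J_err); unmatched residues
    are skipped.  Errors add in quadrature."""
    merged = aligned.merge(
        isotropic, on="residue_id", suffixes=("_aligned", "_iso")
    )
    return pd.DataFrame(
        {
            "residue_id": merged.residue_id,
            "rdc_Hz": merged.J_Hz_aligned - merged.J_Hz_iso,
            "rdc_err": np.sqrt(merged.J_err_aligned**2 + merged.J_err_iso**2),
        }
    )


def _residue_in_ranges(seqid: int, ranges) -> bool:
    return any(lo <= seqid <= hi for lo, hi in ranges)


def amide_bond_vectors(
    structure: gemmi.Structure,
    exclude_ranges: tuple[tuple[int, int], ...] = (),
    model_index: int = 0,
) -> pd.DataFrame:
    """Unit N->H bond vectors per residue over all protein chains of the
    model (the homodimer is fit with one joint tensor).

    When the amide H is absent (crystal structures), it is constructed in
    the peptide plane along the bisector geometry: h_dir = -normalize(
    normalize(CA-N) + normalize(C_prev-N)) from N, CA and the preceding
    carbonyl C.  Chain-initial residues without H are skipped.
    """
    rows = []
    model = structure[model_index]
    for chain in model:
        prev_c = None
        for res in chain:
            n = res.find_atom("N", "*")
            ca = res.find_atom("CA", "*")
            if n is None or ca is None:
                prev_c = None
                continue
            seqid = res.seqid.num
            h = res.find_atom("H", "*") or res.find_atom("HN", "*")
            npos = np.array(n.pos.tolist())
            if h is not None:
                vec = np.array(h.pos.tolist()) - npos
            elif prev_c is not None:
                v1 = np.array(ca.pos.tolist()) - npos
                v2 = prev_c - npos
                v1 /= np.linalg.norm(v1)
                v2 /= np.linalg.norm(v2)
                vec = -(v1 + v2)
            else:
                prev_c = _atom_pos(res, "C")
                continue
            norm = np.linalg.norm(vec)
            if norm > 0 and not _residue_in_ranges(seqid, exclude_ranges):
                u = vec / norm
                rows.append((chain.name, seqid, res.name, *u))
            prev_c = _atom_pos(res, "C")
    return pd.DataFrame(
        rows, columns=["chain", "residue_id", "residue_name", "ux", "uy", "uz"]
    )


def _atom_pos(res, name):
    a = res.find_atom(name, "*")
    return None if a is None else np.array(a.pos.tolist())


def _design_matrix(u: np.ndarray) -> np.ndarray:
    """Rows [uy^2-ux^2, uz^2-ux^2, 2 ux uy, 2 ux uz, 2 uy uz] mapping the
    five independent Saupe elements (Syy, Szz, Sxy, Sxz, Syz; Sxx by
    tracelessness) to u^T S u."""
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    return np.column_stack(
        [uy**2 - ux**2, uz**2 - ux**2, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz]
    )


def _saupe_from_elements(s: np.ndarray) -> np.ndarray:
    syy, szz, sxy, sxz, syz = s
    sxx = -(syy + szz)
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])


@dataclass
class AlignmentResults:
    """Fitted alignment (Saupe) tensor in Hz units with agreement metrics."""

    saupe: np.ndarray  # 3x3 symmetric traceless, Hz
    predicted: pd.DataFrame  # residue_id, rdc_obs, rdc_calc
    pearson_r: float
    q_factor: float
    chisqr: float

    @property
    def eigenvalues(self) -> np.ndarray:
        """Principal values ordered |Azz| >= |Ayy| >= |Axx|."""
        w = np.linalg.eigvalsh(self.saupe)
        return w[np.argsort(np.abs(w))][::-1]

    @property
    def axial(self) -> float:
        """Axial component Da = Azz/2 (Hz)."""
        return float(self.eigenvalues[0] / 2.0)

    @property
    def rhombicity(self) -> float:
        azz, ayy, axx = self.eigenvalues
        return float((axx - ayy) / azz * (2.0 / 3.0))

    def summary(self) -> str:
        return (
            f"Alignment tensor fit: n = {len(self.predicted)}, "
            f"r = {self.pearson_r:.3f}, Q = {self.q_factor:.3f}\n"
            f"  Da = {self.axial:.2f} Hz, rhombicity = {self.rhombicity:.3f}\n"
            f"  Saupe (Hz):\n{np.array_str(self.saupe, precision=3)}"
        )


class AlignmentModel:
    """Order-matrix fit of observed RDCs to bond vectors of one structure.

    ``vectors`` is the output of :func:`amide_bond_vectors` (or any table
    with residue_id, ux, uy, uz).  With a homodimer both protomers' residues
    match the same residue_id and each contributes a row.
    """

    def __init__(self, rdcs: pd.DataFrame, vectors: pd.DataFrame):
        merged = vectors.merge(rdcs, on="residue_id")
        if len(merged) < 5:
            raise ValueError(
                f"need >= 5 residues with RDCs and bond vectors, have {len(merged)}"
            )
        self.data = merged.reset_index(drop=True)

    def fit(self) -> AlignmentResults:
        u = self.data[["ux", "uy", "uz"]].to_numpy(dtype=float)
        d = self.data.rdc_Hz.to_numpy(dtype=float)
        err = self.data.get("rdc_err")
        w = np.ones_like(d)
        if err is not None:
            e = err.to_numpy(dtype=float)
            if np.all(e > 0):
                w = 1.0 / e
        A = _design_matrix(u) * w[:, None]
        if np.linalg.matrix_rank(A) < 5:
            raise DegenerateGeometryError(
                "bond-vector geometry is degenerate (rank-deficient design matrix)"
            )
        s, *_ = np.linalg.lstsq(A, d * w, rcond=None)
        saupe = _saupe_from_elements(s)
        calc = np.einsum("ni,ij,nj->n", u, saupe, u)
        resid = (d - calc) * w
        pred = pd.DataFrame(
            {
                "residue_id": self.data.residue_id,
                "chain": self.data.get("chain", "A"),
                "rdc_obs": d,
                "rdc_calc": calc,
            }
        )
        r = float(np.corrcoef(d, calc)[0, 1]) if len(d) > 2 else float("nan")
        q = float(np.sqrt(np.mean((d - calc) ** 2) / np.mean(d**2)))
        return AlignmentResults(
            saupe=saupe, predicted=pred, pearson_r=r, q_factor=q,
            chisqr=float(np.sum(resid**2)),
        )


def predict_rdcs(saupe: np.ndarray, vectors: pd.DataFrame) -> pd.DataFrame:
    """Back-calculate RDCs for bond vectors from a Saupe tensor (Hz)."""
    u = vectors[["ux", "uy", "uz"]].to_numpy(dtype=float)
    calc = np.einsum("ni,ij,nj->n", u, saupe, u)
    out = vectors[["residue_id"]].copy()
    out["rdc_Hz"] = calc
    return out


def all_atom_rmsd(
    st1: gemmi.Structure, st2: gemmi.Structure, superpose: bool = True
) -> float:
    """All-atom RMSD (A) between two structures over atoms matched by
    (chain, residue number, atom name), optionally after least-squares
    superposition."""
    def atom_map(st):
        out = {}
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    if atom.element != gemmi.Element("H"):
                        out[(chain.name, res.seqid.num, atom.name)] = np.array(
                            atom.pos.tolist()
                        )
        return out

    m1, m2 = atom_map(st1), atom_map(st2)
    keys = sorted(set(m1) & set(m2))
    if len(keys) < 3:
        raise ValueError("fewer than 3 matched atoms between structures")
    x = np.array([m1[k] for k in keys])
    y = np.array([m2[k] for k in keys])
    if superpose:
        x = x - x.mean(axis=0)
        y = y - y.mean(axis=0)
        # Kabsch
        H = x.T @ y
        U, _, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, sign]) @ U.T
        x = x @ R.T
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
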