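"""Finite-element kernels on triangle meshes.

Mixed velocity/pressure spaces for incompressible flow: continuous P2 or P1
velocity with P1 pressure, assembled with numpy-vectorized element loops and
solved with scipy sparse LU.  Supports the planar (x, z) and the axisymmetric
(r, z) weak forms; the latter carries the 2*pi*r measure and the hoop strain
term.  Velocity dofs are blocked: ``u = [u_x(all nodes), u_y(all nodes)]``.

Only simplex (affine) triangles are handled; geometry vertices are P1 and the
quadratic velocity nodes sit at edge midpoints of the current configuration.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh

# degree-5 7-point rule on the reference triangle (barycentric), weights sum 1/2
_TRI7_BARY = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [0.79742698535308732, 0.10128650732345634, 0.10128650732345634],
    [0.10128650732345634, 0.79742698535308732, 0.10128650732345634],
    [0.10128650732345634, 0.10128650732345634, 0.79742698535308732],
    [0.05971587178976982, 0.47014206410511509, 0.47014206410511509],
    [0.47014206410511509, 0.05971587178976982, 0.47014206410511509],
    [0.47014206410511509, 0.47014206410511509, 0.05971587178976982],
])
_TRI7_W = np.array([
    0.225,
    0.12593918054482715, 0.12593918054482715, 0.12593918054482715,
    0.13239415278850618, 0.13239415278850618, 0.13239415278850618,
]) * 0.5

# 3-point Gauss on [0, 1] (degree 5) for boundary facets
_GAUSS3_X = np.array([0.5 - np.sqrt(15) / 10, 0.5, 0.5 + np.sqrt(15) / 10])
_GAUSS3_W = np.array([5 / 18, 8 / 18, 5 / 18])

_GRAD_L = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # barycentric grads


def _basis_p1(bary: np.ndarray) -> np.ndarray:
    return bary.copy()


def _basis_p2(bary: np.ndarray) -> np.ndarray:
    L = bary
    vert = L * (2 * L - 1)
    e01 = 4 * L[:, [0]] * L[:, [1]]
    e12 = 4 * L[:, [1]] * L[:, [2]]
    e20 = 4 * L[:, [2]] * L[:, [0]]
    return np.concatenate([vert, e01, e12, e20], axis=1)


def _grad_p1(bary: np.ndarray) -> np.ndarray:
    nq = bary.shape[0]
    return np.broadcast_to(_GRAD_L, (nq, 3, 2)).copy()


def _grad_p2(bary: np.ndarray) -> np.ndarray:
    L = bary
    nq = L.shape[0]
    G = np.zeros((nq, 6, 2))
    for i in range(3):
        G[:, i] = (4 * L[:, [i]] - 1) * _GRAD_L[i]
    pairs = [(0, 1), (1, 2), (2, 0)]
    for k, (i, j) in enumerate(pairs):
        G[:, 3 + k] = 4 * (L[:, [i]] * _GRAD_L[j] + L[:, [j]] * _GRAD_L[i])
    return G


class Space:
    """Scalar Lagrange space (degree 1 or 2) on a triangle mesh."""

    def __init__(self, mesh: Mesh, degree: int):
        if mesh.dim != 2:
            raise NotImplementedError(
                "finite-element flow solves are implemented for triangle "
                "meshes (2D cross-section and axisymmetric modes)"
            )
        self.mesh = mesh
        self.degree = degree
        cells = mesh.cells
        nv = mesh.n_nodes
        if degree == 1:
            self.cell_dofs = cells.copy()
            self.ndof = nv
            self._edge_of = None
        elif degree == 2:
            pairs = np.concatenate(
                [cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]]
            )
            key = np.sort(pairs, axis=1)
            uniq, inv = np.unique(key, axis=0, return_inverse=True)
            edge_ids = nv + inv.reshape(3, -1).T  # (ne, 3): e01, e12, e20
            self.cell_dofs = np.concatenate([cells, edge_ids], axis=1)
            self.ndof = nv + len(uniq)
            self._edges = uniq
            dt = np.dtype((np.void, uniq.dtype.itemsize * 2))
            self._edge_view = np.ascontiguousarray(uniq).view(dt).ravel()
            self._edge_order = np.argsort(self._edge_view)
        else:
            raise ValueError("degree must be 1 or 2")
        self.nloc = self.cell_dofs.shape[1]
        # boundary facet dofs: (a, b[, midpoint])
        bf = mesh.boundary_facets
        if degree == 1:
            self.facet_dofs = bf.copy()
        else:
            self.facet_dofs = np.concatenate(
                [bf, self._edge_lookup(bf)[:, None]], axis=1
            )

    def _edge_lookup(self, pairs: np.ndarray) -> np.ndarray:
        key = np.sort(pairs, axis=1).astype(self._edges.dtype)
        dt = self._edge_view.dtype
        kview = np.ascontiguousarray(key).view(dt).ravel()
        pos = self._edge_order[
            np.searchsorted(self._edge_view[self._edge_order], kview)
        ]
        return self.mesh.n_nodes + pos

    def dof_coords(self, vertex_coords: np.ndarray) -> np.ndarray:
        if self.degree == 1:
            return vertex_coords
        mids = vertex_coords[self._edges].mean(axis=1)
        return np.vstack([vertex_coords, mids])

    def boundary_dofs(self, patch: str | None = None) -> np.ndarray:
        if patch is None:
            return np.unique(self.facet_dofs)
        idx = self.mesh.facets_of(patch)
        return np.unique(self.facet_dofs[idx])


class Assembler:
    """Vectorized operators for mixed flow problems on one mesh topology.

    Call :meth:`set_coords` whenever the vertex coordinates move (ALE); the
    connectivity, sparsity patterns and quadrature tables are reused.
    """

    def __init__(self, mesh: Mesh, velocity_degree: int = 2,
                 axisymmetric: bool = False):
        self.mesh = mesh
        self.axi = axisymmetric
        self.V = Space(mesh, velocity_degree)
        self.Q = Space(mesh, 1)
        bary = _TRI7_BARY
        self._bv = _basis_p2(bary) if velocity_degree == 2 else _basis_p1(bary)
        self._gv = _grad_p2(bary) if velocity_degree == 2 else _grad_p1(bary)
        self._bq = _basis_p1(bary)
        self._gq = _grad_p1(bary)
        self._wq = _TRI7_W
        # sparsity index tables
        cv, cq = self.V.cell_dofs, self.Q.cell_dofs
        self._rvv = np.repeat(cv, self.V.nloc, axis=1).ravel()
        self._cvv = np.tile(cv, (1, self.V.nloc)).ravel()
        self._rqv = np.repeat(cq, self.V.nloc, axis=1).ravel()
        self._cqv = np.tile(cv, (1, 3)).ravel()
        self._rqq = np.repeat(cq, 3, axis=1).ravel()
        self._cqq = np.tile(cq, (1, 3)).ravel()
        self.set_coords(mesh.points)

    # -- geometry-dependent tables -----------------------------------------

    def set_coords(self, vertex_coords: np.ndarray) -> None:
        self.coords = np.asarray(vertex_coords, float)
        tri = self.coords[self.mesh.cells]
        J = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]], axis=2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            bad = np.nonzero(detJ <= 0)[0]
            raise RuntimeError(
                f"element inversion: {bad[:10].tolist()} (and "
                f"{max(0, bad.size - 10)} more)"
            )
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ /= detJ[:, None, None]
        self._detJ = detJ
        # physical gradients: G[e, q, a, d] = sum_k gref[q, a, k] invJ[e, k, d]
        self.Gv = np.einsum("qak,ekd->eqad", self._gv, invJ)
        self.Gq = np.einsum("qak,ekd->eqad", self._gq, invJ)
        self.xq = np.einsum("qa,ead->eqd", self._bq, tri)  # quad-point coords
        w = self._wq[None, :] * detJ[:, None]
        if self.axi:
            r = self.xq[..., 0]
            if np.any(r < -1e-14):
                raise ValueError("axisymmetric mesh must lie in r >= 0")
            w = w * (2 * np.pi * np.clip(r, 0.0, None))
        self.w = w
        self.vcoords = self.V.dof_coords(self.coords)

    # -- operators ----------------------------------------------------------

    def _vv(self, blocks) -> sp.csr_matrix:
        """Assemble a 2x2-block velocity matrix from per-element kernels."""
        n = self.V.ndof
        mats = []
        for blk in blocks:  # row-major [xx, xy, yx, yy]
            if blk is None:
                mats.append(None)
            else:
                mats.append(sp.coo_matrix(
                    (blk.ravel(), (self._rvv, self._cvv)), shape=(n, n)
                ))
        return sp.bmat([[mats[0], mats[1]], [mats[2], mats[3]]],
                       format="csr")

    def viscous(self, mu: float) -> sp.csr_matrix:
        """mu * int (grad u + grad u^T) : grad v  (+ hoop term if axisym)."""
        G, w = self.Gv, self.w
        gx, gy = G[..., 0], G[..., 1]
        xx = mu * np.einsum("eq,eqa,eqb->eab", w, gx, gx) * 2 \
            + mu * np.einsum("eq,eqa,eqb->eab", w, gy, gy)
        yy = mu * np.einsum("eq,eqa,eqb->eab", w, gy, gy) * 2 \
            + mu * np.einsum("eq,eqa,eqb->eab", w, gx, gx)
        xy = mu * np.einsum("eq,eqa,eqb->eab", w, gy, gx)
        yx = mu * np.einsum("eq,eqa,eqb->eab", w, gx, gy)
        if self.axi:
            r = np.clip(self.xq[..., 0], 1e-30, None)
            N = self._bv
            xx = xx + 2 * mu * np.einsum("eq,qa,qb->eab", w / (r * r), N, N)
        return self._vv([xx, xy, yx, yy])

    def mass(self, coef: float | np.ndarray = 1.0) -> sp.csr_matrix:
        """Vector mass matrix; ``coef`` scalar or per-quad-point array."""
        N = self._bv
        if np.isscalar(coef):
            wq = self.w * coef
        else:
            wq = self.w * coef
        m = np.einsum("eq,qa,qb->eab", wq, N, N)
        return self._vv([m, None, None, m])

    def convection(self, b_nodal: np.ndarray, rho: float,
                   skew: bool = True, upwind: float = 0.0) -> sp.csr_matrix:
        """rho (b . grad u, v) with optional skew and streamline-upwind terms.

        ``b_nodal``: (2, ndof_v) advective velocity at velocity nodes.  The
        skew term 0.5*rho*(div b)(u, v) makes the discrete operator
        energy-neutral, which keeps under-resolved high-Reynolds runs stable
        but undamped; ``upwind`` > 0 adds classical streamline diffusion
        tau_e (b.grad u, b.grad v) with tau_e = upwind * rho * h_e / (2|b|),
        i.e. an effective streamwise viscosity upwind*|b|*h_e/2.  The term
        vanishes wherever b.grad u = 0, so unidirectional verification flows
        (Poiseuille, Womersley, rigid translation) are untouched.
        """
        N, G, w = self._bv, self.Gv, self.w
        cd = self.V.cell_dofs
        bx = np.einsum("qa,ea->eq", N, b_nodal[0][cd])
        by = np.einsum("qa,ea->eq", N, b_nodal[1][cd])
        bdg = bx[..., None] * G[..., 0] + by[..., None] * G[..., 1]  # (e,q,b)
        m = rho * np.einsum("eq,qa,eqb->eab", w, N, bdg)
        if skew:
            divb = np.einsum("eqa,ea->eq", G[..., 0], b_nodal[0][cd]) \
                 + np.einsum("eqa,ea->eq", G[..., 1], b_nodal[1][cd])
            if self.axi:
                r = np.clip(self.xq[..., 0], 1e-30, None)
                divb = divb + bx / r
            m = m + 0.5 * rho * np.einsum("eq,qa,qb->eab", w * divb, N, N)
        if upwind > 0.0:
            bmag = np.sqrt((self.w * (bx ** 2 + by ** 2)).sum(axis=1)
                           / self.w.sum(axis=1))
            h_e = np.sqrt(2.0 * np.abs(self._detJ))
            tau = upwind * rho * h_e / (2.0 * bmag + 1e-30)
            m = m + np.einsum("e,eq,eqa,eqb->eab", tau, w, bdg, bdg)
        return self._vv([m, None, None, m])

    def divergence(self) -> sp.csr_matrix:
        """B with B[q, u] = -int q div(u); continuity rows of the saddle."""
        Nq, G, w = self._bq, self.Gv, self.w
        bx = -np.einsum("eq,qa,eqb->eab", w, Nq, G[..., 0])
        by = -np.einsum("eq,qa,eqb->eab", w, Nq, G[..., 1])
        if self.axi:
            r = np.clip(self.xq[..., 0], 1e-30, None)
            Nv = self._bv
            bx = bx - np.einsum("eq,qa,qb->eab", w / r, Nq, Nv)
        n_p, n_v = self.Q.ndof, self.V.ndof
        Bx = sp.coo_matrix((bx.ravel(), (self._rqv, self._cqv)), shape=(n_p, n_v))
        By = sp.coo_matrix((by.ravel(), (self._rqv, self._cqv)), shape=(n_p, n_v))
        return sp.hstack([Bx, By], format="csr")

    def pressure_mean(self) -> np.ndarray:
        """Vector m with m[q] = int q dx (for the zero-mean constraint)."""
        m = np.zeros(self.Q.ndof)
        vals = np.einsum("eq,qa->ea", self.w, self._bq)
        np.add.at(m, self.Q.cell_dofs, vals)
        return m

    def pressure_laplacian(self, scale_by_h2: bool = True) -> sp.csr_matrix:
        """int h_K^2 grad p . grad q — Brezzi–Pitkaranta stabilization core."""
        G, w = self.Gq, self.w
        k = np.einsum("eq,eqad,eqbd->eab", w, G, G)
        if scale_by_h2:
            tri = self.coords[self.mesh.cells]
            e = np.stack([
                tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]
            ])
            h2 = (np.linalg.norm(e, axis=2) ** 2).max(axis=0)
            k = k * h2[:, None, None]
        return sp.coo_matrix(
            (k.ravel(), (self._rqq, self._cqq)), shape=(self.Q.ndof, self.Q.ndof)
        ).tocsr()

    def load(self, f) -> np.ndarray:
        """Body-force vector; ``f`` is (2,) constant or callable(x) -> (n,2)."""
        N, w = self._bv, self.w
        if callable(f):
            fq = f(self.xq.reshape(-1, 2)).reshape(self.xq.shape)
        else:
            fq = np.broadcast_to(np.asarray(f, float), self.xq.shape)
        Fx = np.einsum("eq,eq,qa->ea", w, fq[..., 0], N)
        Fy = np.einsum("eq,eq,qa->ea", w, fq[..., 1], N)
        out = np.zeros(2 * self.V.ndof)
        np.add.at(out, self.V.cell_dofs, Fx)
        np.add.at(out, self.V.ndof + self.V.cell_dofs, Fy)
        return out

    # -- boundary tables -----------------------------------------------------

    def facet_lumped_mass(self) -> np.ndarray:
        """m_i = int_Gamma phi_i dGamma over the whole boundary (r-weighted
        in axisymmetric mode); used to turn reaction integrals into nodal
        tractions."""
        fd = self.V.facet_dofs
        p = self.coords[self.mesh.boundary_facets]
        L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        s = _GAUSS3_X
        if self.V.degree == 2:
            basis = np.stack([(1 - s) * (1 - 2 * s), s * (2 * s - 1),
                              4 * s * (1 - s)], axis=1)
        else:
            basis = np.stack([1 - s, s], axis=1)
        wq = _GAUSS3_W[None, :] * L[:, None]
        if self.axi:
            rq = p[:, 0, 0][:, None] * (1 - s)[None, :] \
               + p[:, 1, 0][:, None] * s[None, :]
            wq = wq * 2 * np.pi * np.clip(rq, 0.0, None)
        vals = np.einsum("fq,qa->fa", wq, basis)
        m = np.zeros(self.V.ndof)
        np.add.at(m, fd, vals)
        return m

    def nodal_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """(node_ids, unit outward normals) on the boundary, length-weighted
        averages of adjacent facet normals (P2 midpoints get the facet
        normal)."""
        from .geometry import _facet_normals
        fd = self.V.facet_dofs
        fn = _facet_normals(self.coords, self.mesh.boundary_facets)
        p = self.coords[self.mesh.boundary_facets]
        L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        acc = np.zeros((self.V.ndof, 2))
        for a in range(fd.shape[1]):
            np.add.at(acc, fd[:, a], fn * L[:, None])
        ids = np.unique(fd)
        n = acc[ids]
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return ids, n


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------


def saddle_system(A: sp.spmatrix, B: sp.spmatrix,
                  stab: sp.spmatrix | None = None,
                  mean_vec: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble [[A, B^T, 0], [B, -stab, m], [0, m^T, 0]] (blocks optional)."""
    n_p = B.shape[0]
    S = -stab if stab is not None else None
    if mean_vec is not None:
        m = sp.csr_matrix(mean_vec[:, None])
        return sp.bmat([[A, B.T, None], [B, S, m], [None, m.T, None]],
                       format="csc")
    return sp.bmat([[A, B.T], [B, S]], format="csc")


def solve_with_dirichlet(K: sp.spmatrix, F: np.ndarray, fixed: np.ndarray,
                         values: np.ndarray) -> np.ndarray:
    """Solve K x = F with x[fixed] = values via reduction; sparse LU."""
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    K = K.tocsc()
    rhs = F[free] - K[:, fixed][free] @ values
    x = np.zeros(n)
    x[fixed] = values
    x[free] = splu(K[:, free][free]).solve(rhs)
    return x


class DirichletSolver:
    """Reusable reduction for a fixed Dirichlet pattern; refactorize on demand."""

    def __init__(self, n: int, fixed: np.ndarray):
        self.n = n
        self.fixed = np.asarray(fixed, np.int64)
        self.free = np.setdiff1d(np.arange(n), self.fixed)
        self._lu = None
        self._Kfc = None

    def factorize(self, K: sp.spmatrix) -> None:
        K = K.tocsc()
        self._Kfc = K[:, self.fixed][self.free]
        self._lu = splu(K[:, self.free][self.free])

    def solve(self, F: np.ndarray, values: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n)
        x[self.fixed] = values
        x[self.free] = self._lu.solve(F[self.free] - self._Kfc @ values)
        return x
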