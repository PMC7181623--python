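"""Fused per-element kernel for the explicit solver hot loop.

Computes small strain, Hooke stress, von Mises stress, assembled nodal
internal forces, total strain energy, and the bulk-viscosity damping
force in one pass over the elements.  A numba-compiled version is used
when available (serial, hence deterministic); the numpy implementation
is the fallback and the reference for unit cross-checks.

Bulk viscosity follows standard explicit-dynamics practice: a damping
pressure q = a_e tr(deps/dt) with a_e = b1 rho c_d L_e per element,
added to the force assembly only - it is not part of the material
stress, so failure evaluation and stress output see the elastic stress.
The kernel returns the instantaneous viscous dissipation power so the
run's energy ledger can account for it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _compute_numpy(tets, G, V, lam, mu, visc, disp, vel, active):
    u_e = disp[tets]                                   # (E,4,3)
    H = np.matmul(u_e.transpose(0, 2, 1), G)
    eps = 0.5 * (H + H.transpose(0, 2, 1))
    tr = eps[:, 0, 0] + eps[:, 1, 1] + eps[:, 2, 2]
    sig = 2.0 * mu[:, None, None] * eps
    lam_tr = lam * tr
    sig[:, 0, 0] += lam_tr
    sig[:, 1, 1] += lam_tr
    sig[:, 2, 2] += lam_tr
    inact = ~active
    if inact.any():
        sig[inact] = 0.0
        eps[inact] = 0.0

    s11, s22, s33 = sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2]
    s12, s23, s31 = sig[:, 0, 1], sig[:, 1, 2], sig[:, 2, 0]
    vm = np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s31**2)
    )

    # volumetric strain rate and damping pressure
    v_e = vel[tets]
    dvol = np.einsum("eai,eai->e", v_e, G)
    q = visc * dvol
    q[inact] = 0.0
    sig_tot = sig.copy()
    sig_tot[:, 0, 0] += q
    sig_tot[:, 1, 1] += q
    sig_tot[:, 2, 2] += q
    p_visc = float(np.sum(q * dvol * V))

    f_e = -np.matmul(G, sig_tot) * V[:, None, None]    # (E,4,3)
    n = disp.shape[0]
    idx = tets.ravel()
    flat = f_e.reshape(-1, 3)
    f = np.empty((n, 3))
    for i in range(3):
        f[:, i] = np.bincount(idx, weights=flat[:, i], minlength=n)
    se = 0.5 * float(np.einsum("e,eij,eij->", V, sig, eps))
    return f, sig, eps, vm, se, p_visc


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _compute_numba(tets, G, V, lam, mu, visc, disp, vel, active,
                       f, sig, eps, vm):  # pragma: no cover - numba
        n_elem = tets.shape[0]
        n_node = disp.shape[0]
        for p in range(n_node):
            f[p, 0] = 0.0
            f[p, 1] = 0.0
            f[p, 2] = 0.0
        se = 0.0
        p_visc = 0.0
        for e in range(n_elem):
            if not active[e]:
                for i in range(3):
                    for j in range(3):
                        sig[e, i, j] = 0.0
                        eps[e, i, j] = 0.0
                vm[e] = 0.0
                continue
            # H_ij = sum_a u_ai G_aj ; dvol = sum_a v_a . G_a
            h00 = h01 = h02 = h10 = h11 = h12 = h20 = h21 = h22 = 0.0
            dvol = 0.0
            for a in range(4):
                p = tets[e, a]
                u0, u1, u2 = disp[p, 0], disp[p, 1], disp[p, 2]
                g0, g1, g2 = G[e, a, 0], G[e, a, 1], G[e, a, 2]
                h00 += u0 * g0; h01 += u0 * g1; h02 += u0 * g2
                h10 += u1 * g0; h11 += u1 * g1; h12 += u1 * g2
                h20 += u2 * g0; h21 += u2 * g1; h22 += u2 * g2
                dvol += vel[p, 0] * g0 + vel[p, 1] * g1 + vel[p, 2] * g2
            e00, e11, e22 = h00, h11, h22
            e01 = 0.5 * (h01 + h10)
            e12 = 0.5 * (h12 + h21)
            e02 = 0.5 * (h02 + h20)
            tr = e00 + e11 + e22
            lt = lam[e] * tr
            two_mu = 2.0 * mu[e]
            s00 = two_mu * e00 + lt
            s11 = two_mu * e11 + lt
            s22 = two_mu * e22 + lt
            s01 = two_mu * e01
            s12 = two_mu * e12
            s02 = two_mu * e02
            eps[e, 0, 0] = e00; eps[e, 1, 1] = e11; eps[e, 2, 2] = e22
            eps[e, 0, 1] = e01; eps[e, 1, 0] = e01
            eps[e, 1, 2] = e12; eps[e, 2, 1] = e12
            eps[e, 0, 2] = e02; eps[e, 2, 0] = e02
            sig[e, 0, 0] = s00; sig[e, 1, 1] = s11; sig[e, 2, 2] = s22
            sig[e, 0, 1] = s01; sig[e, 1, 0] = s01
            sig[e, 1, 2] = s12; sig[e, 2, 1] = s12
            sig[e, 0, 2] = s02; sig[e, 2, 0] = s02
            vm[e] = np.sqrt(
                0.5 * ((s00 - s11) ** 2 + (s11 - s22) ** 2 + (s22 - s00) ** 2)
                + 3.0 * (s01 * s01 + s12 * s12 + s02 * s02)
            )
            se += 0.5 * V[e] * (
                s00 * e00 + s11 * e11 + s22 * e22
                + 2.0 * (s01 * e01 + s12 * e12 + s02 * e02)
            )
            q = visc[e] * dvol
            p_visc += q * dvol * V[e]
            t00 = s00 + q
            t11 = s11 + q
            t22 = s22 + q
            ve = V[e]
            for a in range(4):
                p = tets[e, a]
                g0, g1, g2 = G[e, a, 0], G[e, a, 1], G[e, a, 2]
                f[p, 0] -= ve * (t00 * g0 + s01 * g1 + s02 * g2)
                f[p, 1] -= ve * (s01 * g0 + t11 * g1 + s12 * g2)
                f[p, 2] -= ve * (s02 * g0 + s12 * g1 + t22 * g2)
        return se, p_visc


def compute(tets, G, V, lam, mu, visc, disp, vel, active):
    """(forces, stress, strain, von Mises, strain energy, viscous power)."""
    if HAVE_NUMBA:
        n_elem, n_node = tets.shape[0], disp.shape[0]
        f = np.empty((n_node, 3))
        sig = np.empty((n_elem, 3, 3))
        eps = np.empty((n_elem, 3, 3))
        vm = np.empty(n_elem)
        se, p_visc = _compute_numba(
            tets, G, V, lam, mu, visc,
            np.ascontiguousarray(disp), np.ascontiguousarray(vel), active,
            f, sig, eps, vm,
        )
        return f, sig, eps, vm, se, p_visc
    return _compute_numpy(tets, G, V, lam, mu, visc, disp, vel, active)
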