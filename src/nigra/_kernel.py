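"""Compiled inner loop of the multicompartment integrator.

One staggered time step advances (1) HH gates by exponential Euler using
voltage lookup tables, (2) the 3-state Markov Na occupancies by an implicit
(backward-Euler) solve of the master equation, (3) the two calcium pools by
exponential Euler, and (4) the voltage by a backward-Euler solve of the cable
equation on the tree (Hines elimination; parents precede children).  An
explicit exponential-Euler voltage update is available for cross-checks.

Units: mV, ms, nA, nF, uS absolute; channel densities mS/cm^2; calcium uM.
Outward membrane current positive.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1

# gate indices (see channels.GATE_NAMES)
(_KDR_N, _KA_A, _KA_B, _HCN_H, _CAT_M, _CAT_H, _CAL_M, _CAL_H, _CAN_M,
 _M_M, _ERG_O) = range(11)
# channel indices (see channels.CHANNEL_NAMES)
_NA, _KDR, _KA, _HCN, _CAT, _CAL, _CAN, _SK, _M, _ERG, _GIRK, _NAL, _KL = range(13)


@njit(cache=True, fastmath=False)
def _lerp(tab, row, idx0, frac):
    return tab[row, idx0] * (1.0 - frac) + tab[row, idx0 + 1] * frac


@njit(cache=True, fastmath=False)
def run_kernel(
    nsteps, dt,
    parent, area, g_ax, cm_nF,
    gdens, erev,
    vmin_tab, vstep_tab, xinf, xexp, mk, mg_tab,
    f_cpl, tau_micro, phi_micro, tau_bulk, phi_bulk, ca_floor, sk_kd, sk_hill,
    syn_rise_exp, syn_decay_exp, syn_e_glut, syn_e_gaba,
    ev_step, ev_comp, ev_wa, ev_wn, ev_wg,
    stim_comp, stim_on, stim_off, stim_nA,
    v, gates, mkst, ca_mic, ca_blk, syn_r, syn_d,
    rec_every, rec_idx, v_out, cur_out, record_currents,
    use_exp_euler_voltage,
):
    n = v.shape[0]
    nv_tab = xinf.shape[1]
    nev = ev_step.shape[0]
    nstim = stim_comp.shape[0]

    gsum = np.empty(n)
    rhs = np.empty(n)
    diag = np.empty(n)
    ev_ptr = 0
    rec_row = 0
    sk_kd_pow = sk_kd ** sk_hill

    for step in range(nsteps):
        recording_now = step % rec_every == 0

        # ---- synaptic events scheduled for this step
        while ev_ptr < nev and ev_step[ev_ptr] == step:
            c = ev_comp[ev_ptr]
            syn_r[0, c] += ev_wa[ev_ptr]
            syn_d[0, c] += ev_wa[ev_ptr]
            syn_r[1, c] += ev_wn[ev_ptr]
            syn_d[1, c] += ev_wn[ev_ptr]
            syn_r[2, c] += ev_wg[ev_ptr]
            syn_d[2, c] += ev_wg[ev_ptr]
            ev_ptr += 1

        # ---- per-compartment mechanism update and linear assembly
        for i in range(n):
            vi = v[i]
            x = (vi - vmin_tab) / vstep_tab
            if x < 0.0:
                x = 0.0
            elif x > nv_tab - 2:
                x = float(nv_tab - 2)
            i0 = int(x)
            fr = x - i0

            # HH gates: exponential Euler toward xinf with tabulated exp(-dt/tau)
            for g in range(11):
                xi = _lerp(xinf, g, i0, fr)
                xe = _lerp(xexp, g, i0, fr)
                gates[g, i] = xi + (gates[g, i] - xi) * xe

            # Markov Na: implicit Euler step of the master equation, solved
            # exactly (3x3 Cramer); preserves the occupancy sum to roundoff
            a = _lerp(mk, 0, i0, fr)
            b = _lerp(mk, 1, i0, fr)
            koi = _lerp(mk, 2, i0, fr)
            kic = _lerp(mk, 3, i0, fr)
            kci = _lerp(mk, 4, i0, fr)
            m00 = 1.0 + dt * (a + kci)
            m01 = -dt * b
            m02 = -dt * kic
            m10 = -dt * a
            m11 = 1.0 + dt * (b + koi)
            m20 = -dt * kci
            m21 = -dt * koi
            m22 = 1.0 + dt * kic
            x0 = mkst[0, i]
            x1 = mkst[1, i]
            x2 = mkst[2, i]
            det = (m00 * (m11 * m22)
                   - m01 * (m10 * m22)
                   + m02 * (m10 * m21 - m11 * m20))
            c0 = x0 * (m11 * m22) - m01 * (x1 * m22) + m02 * (x1 * m21 - m11 * x2)
            c1 = m00 * (x1 * m22) - x0 * (m10 * m22) + m02 * (m10 * x2 - x1 * m20)
            c2 = (m00 * (m11 * x2 - x1 * m21) - m01 * (m10 * x2 - x1 * m20)
                  + x0 * (m10 * m21 - m11 * m20))
            mkst[0, i] = c0 / det
            mkst[1, i] = c1 / det
            mkst[2, i] = c2 / det

            # open fractions
            ng = gates[_KDR_N, i]
            o_kdr = ng * ng * ng
            o_ka = gates[_KA_A, i] * gates[_KA_A, i] * gates[_KA_B, i]
            o_hcn = gates[_HCN_H, i]
            o_cat = gates[_CAT_M, i] * gates[_CAT_M, i] * gates[_CAT_H, i]
            o_cal = gates[_CAL_M, i] * gates[_CAL_H, i]
            o_can = gates[_CAN_M, i] * gates[_CAN_M, i]
            o_m = gates[_M_M, i]
            o_erg = gates[_ERG_O, i]
            ca4 = ca_mic[i] ** sk_hill
            o_sk = ca4 / (ca4 + sk_kd_pow)
            o_na = mkst[1, i]

            # Ca current densities (uA/cm^2) at the pre-step voltage
            i_cat = gdens[_CAT, i] * o_cat * (vi - erev[_CAT])
            i_cal = gdens[_CAL, i] * o_cal * (vi - erev[_CAL])
            i_can = gdens[_CAN, i] * o_can * (vi - erev[_CAN])

            # calcium pools: exponential relaxation toward influx fixed point;
            # microdomain sees CaN plus fraction f of CaT (CaL electrogenic only)
            infl_m = 0.0
            if i_can < 0.0:
                infl_m -= i_can
            if i_cat < 0.0:
                infl_m -= f_cpl * i_cat
            infl_b = 0.0
            if i_can < 0.0:
                infl_b -= i_can
            if i_cat < 0.0:
                infl_b -= i_cat
            if i_cal < 0.0:
                infl_b -= i_cal
            tgt = ca_floor + phi_micro * infl_m * tau_micro
            ca_mic[i] = tgt + (ca_mic[i] - tgt) * np.exp(-dt / tau_micro)
            tgt = ca_floor + phi_bulk * infl_b * tau_bulk
            ca_blk[i] = tgt + (ca_blk[i] - tgt) * np.exp(-dt / tau_bulk)

            # conductance (uS) and g*E (nA) accumulation; density mS/cm^2
            # times area cm^2 times 1e3 gives uS
            sca = area[i] * 1e3
            gtot = 0.0
            ge = 0.0
            g = gdens[_NA, i] * o_na * sca
            gtot += g; ge += g * erev[_NA]
            g = gdens[_KDR, i] * o_kdr * sca
            gtot += g; ge += g * erev[_KDR]
            g = gdens[_KA, i] * o_ka * sca
            gtot += g; ge += g * erev[_KA]
            g = gdens[_HCN, i] * o_hcn * sca
            gtot += g; ge += g * erev[_HCN]
            g = gdens[_CAT, i] * o_cat * sca
            gtot += g; ge += g * erev[_CAT]
            g = gdens[_CAL, i] * o_cal * sca
            gtot += g; ge += g * erev[_CAL]
            g = gdens[_CAN, i] * o_can * sca
            gtot += g; ge += g * erev[_CAN]
            g = gdens[_SK, i] * o_sk * sca
            gtot += g; ge += g * erev[_SK]
            g = gdens[_M, i] * o_m * sca
            gtot += g; ge += g * erev[_M]
            g = gdens[_ERG, i] * o_erg * sca
            gtot += g; ge += g * erev[_ERG]
            g = gdens[_GIRK, i] * sca
            gtot += g; ge += g * erev[_GIRK]
            g = gdens[_NAL, i] * sca
            gtot += g; ge += g * erev[_NAL]
            g = gdens[_KL, i] * sca
            gtot += g; ge += g * erev[_KL]

            # synaptic conductances (uS), bi-exponential g = decay - rise
            g_ampa = syn_d[0, i] - syn_r[0, i]
            g_nmda = (syn_d[1, i] - syn_r[1, i]) * mg_tab[i0]
            g_gaba = syn_d[2, i] - syn_r[2, i]
            gtot += g_ampa + g_nmda + g_gaba
            ge += (g_ampa + g_nmda) * syn_e_glut + g_gaba * syn_e_gaba

            if record_currents and recording_now:
                cur_out[rec_row, _NA] += gdens[_NA, i] * o_na * sca * (vi - erev[_NA])
                cur_out[rec_row, _KDR] += gdens[_KDR, i] * o_kdr * sca * (vi - erev[_KDR])
                cur_out[rec_row, _KA] += gdens[_KA, i] * o_ka * sca * (vi - erev[_KA])
                cur_out[rec_row, _HCN] += gdens[_HCN, i] * o_hcn * sca * (vi - erev[_HCN])
                cur_out[rec_row, _CAT] += i_cat * area[i] * 1e3
                cur_out[rec_row, _CAL] += i_cal * area[i] * 1e3
                cur_out[rec_row, _CAN] += i_can * area[i] * 1e3
                cur_out[rec_row, _SK] += gdens[_SK, i] * o_sk * sca * (vi - erev[_SK])
                cur_out[rec_row, _M] += gdens[_M, i] * o_m * sca * (vi - erev[_M])
                cur_out[rec_row, _ERG] += gdens[_ERG, i] * o_erg * sca * (vi - erev[_ERG])
                cur_out[rec_row, _GIRK] += gdens[_GIRK, i] * sca * (vi - erev[_GIRK])
                cur_out[rec_row, _NAL] += gdens[_NAL, i] * sca * (vi - erev[_NAL])
                cur_out[rec_row, _KL] += gdens[_KL, i] * sca * (vi - erev[_KL])

            gsum[i] = gtot
            rhs[i] = ge

        # ---- synaptic state decay
        for i in range(n):
            syn_r[0, i] *= syn_rise_exp[0]
            syn_d[0, i] *= syn_decay_exp[0]
            syn_r[1, i] *= syn_rise_exp[1]
            syn_d[1, i] *= syn_decay_exp[1]
            syn_r[2, i] *= syn_rise_exp[2]
            syn_d[2, i] *= syn_decay_exp[2]

        # ---- injected currents
        t_ms = step * dt
        for s in range(nstim):
            if stim_on[s] <= t_ms < stim_off[s]:
                rhs[stim_comp[s]] += stim_nA[s]

        if use_exp_euler_voltage:
            # axial currents explicit: fold neighbor voltages into g/gE terms
            for i in range(n):
                p = parent[i]
                if p >= 0:
                    gsum[i] += g_ax[i]
                    rhs[i] += g_ax[i] * v[p]
                    gsum[p] += g_ax[i]
                    rhs[p] += g_ax[i] * v[i]
            for i in range(n):
                gt = gsum[i]
                if gt <= 1e-12:
                    v[i] = v[i] + rhs[i] * dt / cm_nF[i]
                else:
                    vinf = rhs[i] / gt
                    v[i] = vinf + (v[i] - vinf) * np.exp(-dt * gt / cm_nF[i])
        else:
            # ---- backward-Euler voltage solve on the tree (Hines)
            for i in range(n):
                diag[i] = cm_nF[i] / dt + gsum[i]
                rhs[i] += cm_nF[i] / dt * v[i]
            for i in range(n):
                p = parent[i]
                if p >= 0:
                    diag[i] += g_ax[i]
                    diag[p] += g_ax[i]
            for i in range(n - 1, 0, -1):
                p = parent[i]
                f = g_ax[i] / diag[i]
                diag[p] -= f * g_ax[i]
                rhs[p] += f * rhs[i]
            v[0] = rhs[0] / diag[0]
            for i in range(1, n):
                v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        # ---- divergence guard
        for i in range(n):
            if not (-200.0 < v[i] < 200.0):
                return STATUS_DIVERGED, step

        # ---- recording (post-update voltage)
        if recording_now:
            for k in range(rec_idx.shape[0]):
                v_out[rec_row, k] = v[rec_idx[k]]
            rec_row += 1

    return STATUS_OK, nsteps
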