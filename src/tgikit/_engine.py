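"""Vectorized trajectory evaluation for a fixed cohort design.

The per-interval closed form makes the prediction at any observation time an
affine function of the individual growth rate:

    y(t) = y0 * A(t; E...) + r_i * B(t; E...)

where, chaining K constant-dose segments of durations d_k and effects E_k,

    A = prod_k exp(-E_k d_k)
    B is accumulated by  B <- B * a_k + b_k,   b_k = (1 - a_k) / E_k
      (b_k -> d_k as E_k -> 0; the linear branch is used for |E_k| < 1e-12).

A and B depend only on the drug-effect parameters, so profiling the additive
growth-rate random effect in the mixed-effects objective is exact and cheap.
The engine pre-decomposes every post-baseline observation of a cohort into a
padded (n_obs, S) array of segment durations and dose codes once, after
which batched evaluation over all patients is pure array arithmetic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import LINEAR_EFFECT_TOL, PatientRecord

_EXP_CLIP = 50.0  # clip -E*d exponents; beyond this the optimizer is lost anyway

# dose codes
_CODE = {0.0: 0, 5.0: 1, 10.0: 2}


class TrajectoryEngine:
    """Batched predictor y = y0*A + r*B for all post-baseline observations
    of a cohort, under the cohort's fixed dosing histories."""

    def __init__(self, patients: Sequence[PatientRecord]):
        self.patients = list(patients)
        self.n_pat = len(self.patients)
        durs: list[list[float]] = []
        codes: list[list[int]] = []
        pat_idx: list[int] = []
        y_obs: list[float] = []
        t_obs: list[float] = []
        for i, p in enumerate(self.patients):
            for o in p.post_baseline:
                segs = p.dosing.segments(o.time)
                durs.append([d for d, _ in segs])
                codes.append([_CODE[dose] for _, dose in segs])
                pat_idx.append(i)
                y_obs.append(o.sld)
                t_obs.append(o.time)
        self.n_obs = len(y_obs)
        S = max((len(d) for d in durs), default=1)
        self.dur = np.zeros((self.n_obs, S))
        self.code = np.zeros((self.n_obs, S), dtype=np.int8)
        for j, (d, c) in enumerate(zip(durs, codes)):
            self.dur[j, : len(d)] = d
            self.code[j, : len(c)] = c
        self.pat = np.asarray(pat_idx, dtype=np.intp)
        self.y = np.asarray(y_obs)
        self.t = np.asarray(t_obs)
        self.y0 = np.asarray([p.baseline_sld for p in self.patients])
        self.y0_obs = self.y0[self.pat] if self.n_obs else np.empty(0)
        self.n_per_pat = np.bincount(self.pat, minlength=self.n_pat).astype(float)
        self._is5 = self.code == 1
        self._is10 = self.code == 2

    def sum_by_patient(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.pat, weights=values, minlength=self.n_pat)

    def AB(self, e10: np.ndarray, e5: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Affine coefficients per observation for per-patient drug effects."""
        if self.n_obs == 0:
            z = np.empty(0)
            return z, z
        e10o = np.asarray(e10)[self.pat][:, None]
        e5o = np.asarray(e5)[self.pat][:, None]
        E = np.where(self._is10, e10o, 0.0) + np.where(self._is5, e5o, 0.0)
        x = np.clip(-E * self.dur, -_EXP_CLIP, _EXP_CLIP)
        a = np.exp(x)
        small = np.abs(E) < LINEAR_EFFECT_TOL
        # b = (1-a)/E, -> dur in the small-|E| limit
        b = np.where(small, self.dur, (1.0 - a) / np.where(small, 1.0, E))
        A = np.ones(self.n_obs)
        B = np.zeros(self.n_obs)
        for k in range(self.dur.shape[1]):
            A *= a[:, k]
            B = B * a[:, k] + b[:, k]
        return A, B

    def predict(
        self, r: np.ndarray, e10: np.ndarray, e5: np.ndarray
    ) -> np.ndarray:
        """Predicted SLD at every post-baseline observation."""
        A, B = self.AB(e10, e5)
        return self.y0_obs * A + np.asarray(r)[self.pat] * B

    def AB_grad(self, e10: np.ndarray, e5: np.ndarray):
        """A, B and their exact derivatives w.r.t. the patient's e10 and e5.

        Chains d a_k/dE = -d_k a_k and d b_k/dE = (d_k a_k - b_k)/E (with
        the -d_k^2/2 limit at small |E|) through the segment recursion.
        Returns (A, B, dA10, dB10, dA5, dB5); for a tied drug effect the
        derivative w.r.t. the common e is dA10 + dA5 (resp. dB).
        """
        if self.n_obs == 0:
            z = np.empty(0)
            return z, z, z, z, z, z
        e10o = np.asarray(e10)[self.pat][:, None]
        e5o = np.asarray(e5)[self.pat][:, None]
        E = np.where(self._is10, e10o, 0.0) + np.where(self._is5, e5o, 0.0)
        x = np.clip(-E * self.dur, -_EXP_CLIP, _EXP_CLIP)
        a = np.exp(x)
        small = np.abs(E) < LINEAR_EFFECT_TOL
        Esafe = np.where(small, 1.0, E)
        b = np.where(small, self.dur, (1.0 - a) / Esafe)
        da = -self.dur * a
        db = np.where(small, -0.5 * self.dur**2, (self.dur * a - b) / Esafe)
        A = np.ones(self.n_obs)
        B = np.zeros(self.n_obs)
        dA10 = np.zeros(self.n_obs)
        dB10 = np.zeros(self.n_obs)
        dA5 = np.zeros(self.n_obs)
        dB5 = np.zeros(self.n_obs)
        for k in range(self.dur.shape[1]):
            ak, bk = a[:, k], b[:, k]
            da10 = np.where(self._is10[:, k], da[:, k], 0.0)
            da5 = np.where(self._is5[:, k], da[:, k], 0.0)
            db10 = np.where(self._is10[:, k], db[:, k], 0.0)
            db5 = np.where(self._is5[:, k], db[:, k], 0.0)
            dA10, dA5 = dA10 * ak + A * da10, dA5 * ak + A * da5
            dB10 = dB10 * ak + B * da10 + db10
            dB5 = dB5 * ak + B * da5 + db5
            A = A * ak
            B = B * ak + bk
        return A, B, dA10, dB10, dA5, dB5
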