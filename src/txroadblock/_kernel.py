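"""Compiled core of the roadblock traffic simulator.

One fixed-time-step lattice update, iterated inside a single numba-compiled
function.  Coordinates are 1-based bp with the transcription start at +1;
an RNAP with front f occupies [f - footprint + 1, f].  The operator spans
[spacer + 1, spacer + operator_length].  Per step (dt), in fixed order:

1. promoter firing (Bernoulli, 1 - exp(-k_F dt)) if no footprint overlaps
   the occlusion position (+5); the new front starts there;
2. operator kinetics: binding if vacant and unoccluded; unbinding if bound
   (an unbinding under the roadblock-paused leader resumes it: escape);
3. dislodgement attempt by the roadblock-paused leader, at k_SD when alone
   and k_MD when >=1 trailing RNAP is queued in contact (or, under the
   alternative queue rule, when any trailing RNAP is paused);
4. termination: every paused RNAP at k_T (standard), or only the
   promoter-proximal paused RNAP (termination-protection variant);
5. advancement by 1 bp for every RNAP not blocked by the bound roadblock
   (front = spacer) or by a 30 bp headway constraint; blocked RNAPs are
   paused.  A front crossing the operator's downstream edge records a pass;
   the RNAP remains on the lattice (still occluding the operator) until its
   rear clears.

Two uneventful states are advanced by exact exponential waits instead of
stepping: the empty lattice (competing firing and operator
binding/unbinding) and a single RNAP paused at the bound roadblock
(competing firing, escape, single dislodgement and termination).  The
output distribution is unchanged to O(dt).
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


# vacancy causes
VC_NEVER_BOUND = 0
VC_SPONTANEOUS = 1
VC_DISLODGED_SINGLE = 2
VC_DISLODGED_MULTIPLE = 3

# per-RNAP resume causes
RC_NONE = 0
RC_SD = 1
RC_MD = 2
RC_ESCAPE = 3

# pass labels
LAB_SD = 0
LAB_MD = 1
LAB_ESCAPE = 2
LAB_ABSENCE = 3
LAB_OCCLUSION = 4
LAB_FA = 5

LABEL_NAMES = ("SD", "MD", "escape", "absence", "occlusion",
               "facilitated_absence")

# indices into the result vector
R_FIRES = 0
R_PASSES = 1
R_TERMS = 2
R_LAB0 = 3  # .. R_LAB0+5
R_ON_LATTICE = 9
R_TIME = 10
R_TIME_BOUND = 11
R_TIME_CLOGGED = 12
R_SIZE = 13


def _run(k_F, k_B, k_U, k_T, k_SD, k_MD,
         spacer, op_len, footprint, occl_pos, dt,
         t_max, target_fires, burn_in, seed,
         termination_protection, queue_any_paused,
         record, labels, times, ids, check):
    """Run one trajectory; returns the counter vector (see R_* indices)."""
    np.random.seed(seed)
    op_start = spacer + 1
    op_end = spacer + op_len
    exit_pos = op_end + footprint
    maxr = exit_pos // footprint + 2

    pos = np.zeros(maxr, np.int64)
    paused = np.zeros(maxr, np.bool_)
    cause = np.zeros(maxr, np.int8)
    rid = np.zeros(maxr, np.int64)
    count = 0
    next_id = 0

    bound = k_B > 0.0  # start at the (near-stationary) bound state
    vac_cause = VC_NEVER_BOUND
    cont_occl = False  # operator continuously occluded since last pass

    fires = 0
    passes = 0
    terms = 0
    nlab = np.zeros(6, np.int64)
    t = 0.0
    t0 = 0.0
    t_bound = 0.0
    t_clog = 0.0
    burned = burn_in <= 0.0

    p_F = 1.0 - np.exp(-k_F * dt)
    p_B = 1.0 - np.exp(-k_B * dt)
    p_U = 1.0 - np.exp(-k_U * dt)
    p_T = 1.0 - np.exp(-k_T * dt)
    p_SD = 1.0 - np.exp(-k_SD * dt)
    p_MD = 1.0 - np.exp(-k_MD * dt)

    while True:
        if burned and target_fires > 0 and fires >= target_fires:
            break
        if burned and target_fires <= 0 and t >= t_max - 1e-12:
            break

        if count == 0:
            # --- Gillespie jump: empty lattice, 2-state operator + firing
            rate_t = k_U if bound else k_B
            t_fire = np.random.exponential(1.0 / k_F) if k_F > 0.0 else -1.0
            t_tog = np.random.exponential(1.0 / rate_t) if rate_t > 0.0 else -1.0
            if t_fire < 0.0 and t_tog < 0.0:
                # absorbing: nothing can ever happen again
                if target_fires > 0:
                    break
                if bound:
                    t_bound += t_max - t
                t = t_max
                break
            if t_fire < 0.0:
                wait = t_tog
                do_fire = False
            elif t_tog < 0.0:
                wait = t_fire
                do_fire = True
            elif t_fire <= t_tog:
                wait = t_fire
                do_fire = True
            else:
                wait = t_tog
                do_fire = False
            cont_occl = False  # empty lattice: operator not occluded
            if not burned and t + wait >= burn_in:
                # cross the burn-in boundary; exponential waits are
                # memoryless, so redrawing after the reset is exact
                if bound:
                    t_bound += burn_in - t
                t = burn_in
                fires = 0
                passes = 0
                terms = 0
                nlab[:] = 0
                t_bound = 0.0
                t_clog = 0.0
                t0 = t
                burned = True
                continue
            if burned and target_fires <= 0 and t + wait >= t_max:
                if bound:
                    t_bound += t_max - t
                t = t_max
                break
            if bound:
                t_bound += wait
            t += wait
            if do_fire:
                pos[0] = occl_pos
                paused[0] = False
                cause[0] = RC_NONE
                rid[0] = next_id
                next_id += 1
                count = 1
                fires += 1
            else:
                if bound:
                    bound = False
                    vac_cause = VC_SPONTANEOUS
                else:
                    bound = True
            continue

        if count == 1 and paused[0] and bound and pos[0] == spacer:
            # --- Gillespie jump: lone RNAP stalled at the bound roadblock.
            # Competing exponentials: promoter firing (if unoccluded),
            # escape by spontaneous unbinding, single dislodgement,
            # termination.  The operator is vacant of RNAP here, so the
            # occlusion-continuity flag drops exactly as under stepping.
            in_promoter_window = (occl_pos <= pos[0]
                                  <= occl_pos + footprint - 1)
            r_F = 0.0 if in_promoter_window else k_F
            total = r_F + k_U + k_SD + k_T
            cont_occl = False
            if total <= 0.0:
                # absorbing: the pause can never resolve and nothing fires
                if target_fires > 0:
                    break
                t_bound += t_max - t
                if in_promoter_window:
                    t_clog += t_max - t
                t = t_max
                break
            wait = np.random.exponential(1.0 / total)
            if not burned and t + wait >= burn_in:
                t = burn_in
                fires = 0
                passes = 0
                terms = 0
                nlab[:] = 0
                t_bound = 0.0
                t_clog = 0.0
                t0 = t
                burned = True
                continue
            if burned and target_fires <= 0 and t + wait >= t_max:
                t_bound += t_max - t
                if in_promoter_window:
                    t_clog += t_max - t
                t = t_max
                break
            t += wait
            t_bound += wait
            if in_promoter_window:
                t_clog += wait
            u = np.random.random() * total
            if u < r_F:
                pos[count] = occl_pos
                paused[count] = False
                cause[count] = RC_NONE
                rid[count] = next_id
                next_id += 1
                count += 1
                fires += 1
            elif u < r_F + k_U:
                bound = False
                vac_cause = VC_SPONTANEOUS
                paused[0] = False
                cause[0] = RC_ESCAPE
            elif u < r_F + k_U + k_SD:
                bound = False
                vac_cause = VC_DISLODGED_SINGLE
                paused[0] = False
                cause[0] = RC_SD
            else:
                terms += 1
                count = 0
            continue

        # --- fixed-dt stepped update -----------------------------------
        # (1) promoter firing
        occl5 = False
        for i in range(count):
            if occl_pos <= pos[i] <= occl_pos + footprint - 1:
                occl5 = True
        if k_F > 0.0 and not occl5 and np.random.random() < p_F:
            pos[count] = occl_pos
            paused[count] = False
            cause[count] = RC_NONE
            rid[count] = next_id
            next_id += 1
            count += 1
            fires += 1

        # operator occlusion by any footprint
        occl = False
        for i in range(count):
            if op_start <= pos[i] <= op_end + footprint - 1:
                occl = True

        # (2) operator binding / unbinding
        if bound:
            if k_U > 0.0 and np.random.random() < p_U:
                bound = False
                vac_cause = VC_SPONTANEOUS
                if count > 0 and paused[0] and pos[0] == spacer:
                    paused[0] = False
                    cause[0] = RC_ESCAPE
        else:
            if k_B > 0.0 and not occl and np.random.random() < p_B:
                bound = True

        # (3) dislodgement by the roadblock-paused leader
        if bound and count > 0 and paused[0] and pos[0] == spacer:
            queued = False
            if queue_any_paused:
                for i in range(1, count):
                    if paused[i]:
                        queued = True
            else:
                if count > 1 and pos[0] - pos[1] == footprint:
                    queued = True
            p_dis = p_MD if queued else p_SD
            if p_dis > 0.0 and np.random.random() < p_dis:
                bound = False
                paused[0] = False
                if queued:
                    vac_cause = VC_DISLODGED_MULTIPLE
                    cause[0] = RC_MD
                else:
                    vac_cause = VC_DISLODGED_SINGLE
                    cause[0] = RC_SD

        # (4) termination of paused RNAPs
        if k_T > 0.0:
            if termination_protection:
                idx = -1
                for i in range(count):
                    if paused[i]:
                        idx = i  # promoter-proximal = rearmost paused
                if idx >= 0 and np.random.random() < p_T:
                    for j in range(idx, count - 1):
                        pos[j] = pos[j + 1]
                        paused[j] = paused[j + 1]
                        cause[j] = cause[j + 1]
                        rid[j] = rid[j + 1]
                    count -= 1
                    terms += 1
            else:
                i = 0
                while i < count:
                    if paused[i] and np.random.random() < p_T:
                        for j in range(i, count - 1):
                            pos[j] = pos[j + 1]
                            paused[j] = paused[j + 1]
                            cause[j] = cause[j + 1]
                            rid[j] = rid[j + 1]
                        count -= 1
                        terms += 1
                    else:
                        i += 1

        # (5) advancement, leading RNAP first
        for i in range(count):
            blocked = False
            if pos[i] == spacer and bound:
                blocked = True
            elif i > 0 and pos[i - 1] - pos[i] < footprint + 1:
                blocked = True
            if blocked:
                paused[i] = True
            else:
                pos[i] += 1
                paused[i] = False
                if pos[i] == op_end + 1:
                    # this RNAP's front just cleared the operator: a pass
                    if cause[i] == RC_SD:
                        lab = LAB_SD
                    elif cause[i] == RC_MD:
                        lab = LAB_MD
                    elif cause[i] == RC_ESCAPE:
                        lab = LAB_ESCAPE
                    elif cont_occl:
                        lab = LAB_OCCLUSION
                    elif (vac_cause == VC_DISLODGED_SINGLE
                          or vac_cause == VC_DISLODGED_MULTIPLE):
                        lab = LAB_FA
                    else:
                        lab = LAB_ABSENCE
                    nlab[lab] += 1
                    if record and passes < labels.shape[0]:
                        labels[passes] = lab
                        times[passes] = t
                        ids[passes] = rid[i]
                    passes += 1
                    cont_occl = True  # passer itself now covers the operator

        # retire the leader once its rear clears the operator
        if count > 0 and pos[0] >= exit_pos:
            for j in range(0, count - 1):
                pos[j] = pos[j + 1]
                paused[j] = paused[j + 1]
                cause[j] = cause[j + 1]
                rid[j] = rid[j + 1]
            count -= 1

        # bookkeeping
        occl = False
        clog = False
        for i in range(count):
            if op_start <= pos[i] <= op_end + footprint - 1:
                occl = True
            if paused[i] and occl_pos <= pos[i] <= occl_pos + footprint - 1:
                clog = True
        if not occl:
            cont_occl = False
        t += dt
        if bound:
            t_bound += dt
        if clog:
            t_clog += dt

        if check:
            for i in range(1, count):
                assert pos[i - 1] - pos[i] >= footprint, "footprint overlap"
            assert count <= maxr, "lattice overfull"

        if not burned and t >= burn_in:
            fires = 0
            passes = 0
            terms = 0
            nlab[:] = 0
            t_bound = 0.0
            t_clog = 0.0
            t0 = t
            burned = True

    out = np.zeros(R_SIZE, np.float64)
    out[R_FIRES] = fires
    out[R_PASSES] = passes
    out[R_TERMS] = terms
    for k in range(6):
        out[R_LAB0 + k] = nlab[k]
    out[R_ON_LATTICE] = count
    out[R_TIME] = t - t0
    out[R_TIME_BOUND] = t_bound
    out[R_TIME_CLOGGED] = t_clog
    return out


#: Uncompiled reference implementation (runs the per-step asserts cheaply).
run_kernel_py = _run

run_kernel = njit(cache=True)(_run) if NUMBA else _run
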