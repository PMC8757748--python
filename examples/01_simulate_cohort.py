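"""Generate a small synthetic cohort and look at its hidden structure.

Each participant carries a stiffness coefficient c (mmHg*ms) so that
SBP = c / PTT; the five stiffness classes occupy disjoint coefficient
ranges at population ratio 1:1:3:3:2. Sessions follow the protocol
reference - device record - reference, with two observers per reference
rounded to the nearest 2 mmHg.
"""

from cufflessbp import CohortConfig, generate_cohort
from cufflessbp.simulate import cohort_profiles

cohort = generate_cohort(CohortConfig(n_participants=10, n_extra_sessions=0),
                         rng_seed=1, check_quotas=False)
profiles = cohort_profiles(cohort)

print(f"{len(profiles)} participants, {len(cohort)} sessions\n")
print("pid    class  c (mmHg*ms)  setpoint SBP  example session")
for pid, p in sorted(profiles.items()):
    s = next(x for x in cohort if x.participant_id == pid)
    print(f"{pid}    {p.stiffness_class}    {p.ptt_coefficient:8.0f}   "
          f"{p.bp_setpoint_sbp:8.1f}      "
          f"SBP {s.true_sbp:.1f} / PTT {s.true_ptt:.0f} ms "
          f"(obs1 reads {s.ref_before.obs1_sbp})")

# The product SBP x PTT recovers the participant coefficient exactly:
s0 = cohort[0]
print("\nSBP x PTT =", round(s0.true_sbp * s0.true_ptt, 1),
      "vs coefficient", profiles[s0.participant_id].ptt_coefficient)
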