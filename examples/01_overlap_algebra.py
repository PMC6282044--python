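"""Overlap algebra: from boundary overlaps to integer-ratio category systems.

Builds the canonical sub-second category system and shows the two identities
that pin adjacent-mean ratios: the ratio formula of the overlap parameters,
and the density-equality (intersection) identity.
"""

import rhythmprior as rp

# Worked two-category example: means 100 and 200 ms, upper overlap 2.5 SDs.
# The intersection identity fixes the second category's lower overlap.
c_lower = rp.solve_c_lower(c_upper=2.5, r=200 / 100)
print(f"c_lower for a 100/200 ms pair with c_upper=2.5: {c_lower:.4f}")

# Jointly solving BOTH constraints at the empirical Weber fraction s=0.025
# asks: which overlap pair makes a ratio-2 boundary an equal-density crossing?
ov = rp.joint_solve_overlap(s=0.025, r=2.0)
print(f"joint overlap pair for r=2 at s=0.025: "
      f"c_upper={ov.c_upper:.4f}, c_lower_next={ov.c_lower_next:.4f}")
print(f"ratio check: {rp.ratio_from_overlap(0.025, ov):.6f}")

# The mean recursion under the 1000 ms bound yields the 200/400/800 system.
system = rp.build_category_system(mu_1=200.0, s=0.025, schedule=ov)
print(f"category means (ms): {system.means}, K={system.K}")
print(f"scalar SDs (ms):     {system.sds}")
print("Adjacent means double; the 13-SD overlaps mean the categories are"
      " far apart relative to their scalar spreads.")
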