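"""U-U pair typing (I-VI) and conformation clustering.

Crystallographic surveys group 1x1 uridine internal loops into six types by
hydrogen-bond count (0/1/2) and inclination toward the major or minor
groove.  perturb_uu re-poses a pair to any target type; classify_uu reads
the type back from geometry alone.
"""

import cugdyn as cd

capped = cd.build_cug_duplex(2, cap="GC")   # the MD model system: G(CUG)2C
print("duplex:", capped.chains[0].sequence, "/", capped.chains[1].sequence)
print(f"{len(cd.find_uu_pairs(capped))} U-U pairs\n")

print("type  bonds  inclination  displacement  C1'-C1'")
for target in ("I", "II", "III", "IV", "V", "VI"):
    posed = cd.perturb_uu(capped, 0, target)
    cls = cd.classify_uu(cd.find_uu_pairs(posed)[0])
    print(f"  {cls.type_label:<4} {cls.n_hbonds:^5}  {cls.inclination:<11} "
          f"{cls.displacement:+10.2f} A {cls.c1c1_distance:8.2f} A")

# a trajectory alternating between two poses clusters 50/50
frames = [cd.perturb_uu(capped, 0, "I")] * 10 + \
         [cd.perturb_uu(capped, 0, "VI")] * 10
result = cd.cluster_uu_trajectory(frames, 0, threshold=2.5)
print(f"\naverage-linkage clustering of a two-pose trajectory: "
      f"{result.n_clusters} clusters, populations "
      f"{[round(float(p), 2) for p in result.populations]}")
print("Type IV (one bond, major groove) is the pose crystal structures "
      "report most often; the stretched wobble the builder starts from is "
      "its un-inclined precursor.")
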