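# Occlusion experiments on the right anterior circulation.
#
# 1–3 occlude at/below the Circle of Willis; 4a–4h move the occlusion
# distally through the MCA: the main stem (4a), the superior division and
# its stem branches (4b–4e), and the inferior division and its stem
# branches (4f–4h).  Experiment 4d occludes both distal stems of the
# superior division; in 4e only the stem supplying the central and the
# anterior/posterior parietal arteries is occluded, so the central artery
# keeps its second stem of origin.
experiments:
  "1":  ["R-ICA"]
  "2":  ["R-ICA", "R-M1"]
  "3":  ["R-ICA", "R-A1", "R-M1"]
  "4a": ["R-M1"]
  "4b": ["R-sup-trunk"]
  "4c": ["R-sup-trunk-d1"]
  "4d": ["R-stem-s2", "R-stem-s3"]
  "4e": ["R-stem-s3", "R-stem-s3-distal"]
  "4f": ["R-inf-trunk"]
  "4g": ["R-inf-trunk-d1"]
  "4h": ["R-inf-trunk-d2"]
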