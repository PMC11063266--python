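# Default corridor topology for the retro-condylar route to the inferior
# clivus.  Eleven landmarks (a..k) generate seventeen candidate aperture
# windows; twelve retained corridor tetrahedra (paths) chain into exactly
# seven face-adjacent plans from the posterolateral entry window (abc) to
# the clival target window (ijk).  Three plans are the named approaches:
#   ita  - infra-tubercle: swings below the jugular tubercle via the
#          condylar margin (d) and vertebral-artery entry corridor
#   tta  - trans-tubercle: crosses the tubercle apex (f); includes the
#          corridor segment cfij
#   sta  - supra-tubercle: climbs over the tubercle via the jugular
#          foramen shelf toward the upper clival face
# Landmark roles (default phantom placement; ids themselves are arbitrary):
#   a  posterolateral entry, retroauricular point       (entry window)
#   b  posterolateral entry, retrosigmoid point          (entry window)
#   c  posterior rim of the foramen magnum               (entry window)
#   d  posterosuperior margin of the occipital condyle
#   e  vertebral-artery dural entry point
#   f  jugular tubercle apex                             (tubercle landmark)
#   g  hypoglossal canal opening
#   h  dome of the jugular bulb
#   i  mid-clival target point                           (target window)
#   j  inferior clival target point                      (target window)
#   k  petroclival / jugular foramen target point        (target window)
schema: 1
name: inferior-clivus-default
landmarks: [a, b, c, d, e, f, g, h, i, j, k]
tubercle_landmark: f
start_window: abc
end_window: ijk
windows:
  # junction windows: entry/exit faces of the retained corridor tetrahedra
  - {id: abc, landmarks: [a, b, c]}
  - {id: abi, landmarks: [a, b, i]}
  - {id: acd, landmarks: [a, c, d]}
  - {id: ace, landmarks: [a, c, e]}
  - {id: acj, landmarks: [a, c, j]}
  - {id: bfi, landmarks: [b, f, i]}
  - {id: cij, landmarks: [c, i, j]}
  - {id: fij, landmarks: [f, i, j]}
  - {id: ijk, landmarks: [i, j, k]}
  # additional candidate apertures enumerated during corridor curation;
  # their pairings were rejected (blocked by bone or neurovascular tissue)
  # but they remain part of the window inventory
  - {id: abd, landmarks: [a, b, d]}
  - {id: adj, landmarks: [a, d, j]}
  - {id: bfh, landmarks: [b, f, h]}
  - {id: cdg, landmarks: [c, d, g]}
  - {id: cfi, landmarks: [c, f, i]}
  - {id: dgj, landmarks: [d, g, j]}
  - {id: fhi, landmarks: [f, h, i]}
  - {id: fjk, landmarks: [f, j, k]}
paths:
  - {id: abcd, landmarks: [a, b, c, d], entry_window: abc, exit_window: acd}
  - {id: abce, landmarks: [a, b, c, e], entry_window: abc, exit_window: ace}
  - {id: abci, landmarks: [a, b, c, i], entry_window: abc, exit_window: abi}
  - {id: abfi, landmarks: [a, b, f, i], entry_window: abi, exit_window: bfi}
  - {id: acde, landmarks: [a, c, d, e], entry_window: ace, exit_window: acd}
  - {id: acdj, landmarks: [a, c, d, j], entry_window: acd, exit_window: acj}
  - {id: acej, landmarks: [a, c, e, j], entry_window: ace, exit_window: acj}
  - {id: acij, landmarks: [a, c, i, j], entry_window: acj, exit_window: cij}
  - {id: bfij, landmarks: [b, f, i, j], entry_window: bfi, exit_window: fij}
  - {id: cfij, landmarks: [c, f, i, j], entry_window: cij, exit_window: fij}
  - {id: cijk, landmarks: [c, i, j, k], entry_window: cij, exit_window: ijk}
  - {id: fijk, landmarks: [f, i, j, k], entry_window: fij, exit_window: ijk}
plans:
  - {id: ita, approach: ITA, paths: [abcd, acdj, acij, cijk]}
  - {id: tta, approach: TTA, paths: [abce, acej, acij, cfij, fijk]}
  - {id: sta, approach: STA, paths: [abci, abfi, bfij, fijk]}
  - {id: var-df, paths: [abcd, acdj, acij, cfij, fijk]}
  - {id: var-e, paths: [abce, acej, acij, cijk]}
  - {id: var-ed, paths: [abce, acde, acdj, acij, cijk]}
  - {id: var-edf, paths: [abce, acde, acdj, acij, cfij, fijk]}
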