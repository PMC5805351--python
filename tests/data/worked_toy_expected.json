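{
  "_comment": "Hand-enumerated expectations for the worked toy knowledgebase. db_ids: 1 protein alpha, 2 protein beta, 3 protein gamma, 4 small molecule, 5 gamma-like set, 6 alpha:beta complex, 7 signalling complex, 8 reaction r1, 9 catalyst activity, 10 reaction r2, 11 regulation, 12 reaction r3, 13 subpathway, 14 top pathway.",
  "decompositions": {
    "1": {"without_candidates": [1], "with_candidates": [1]},
    "4": {"without_candidates": [4], "with_candidates": [4]},
    "5": {"without_candidates": [3], "with_candidates": [3, 4]},
    "6": {"without_candidates": [1, 2], "with_candidates": [1, 2]},
    "7": {"without_candidates": [1, 2, 3], "with_candidates": [1, 2, 3, 4]}
  },
  "reaction_io": {
    "8": {"inputs": [1, 2], "outputs": [6]},
    "10": {"inputs": [6, 5], "outputs": [7]},
    "12": {"inputs": [7], "outputs": [4]}
  },
  "ancestor_chains": {
    "8": [[14, 13, 8]],
    "12": [[14, 12]],
    "13": [[14, 13]],
    "14": [[14]]
  },
  "top_pathway_participants_stated": {
    "1": {"roles": ["input", "regulator"], "via": [8, 12]},
    "2": {"roles": ["input"], "via": [8]},
    "4": {"roles": ["catalyst", "output"], "via": [10, 12]},
    "5": {"roles": ["input"], "via": [10]},
    "6": {"roles": ["input", "output"], "via": [8, 10]},
    "7": {"roles": ["input", "output"], "via": [10, 12]}
  },
  "top_pathway_participants_decomposed": {
    "1": {"roles": ["input", "output", "regulator"], "via": [8, 10, 12]},
    "2": {"roles": ["input", "output"], "via": [8, 10, 12]},
    "3": {"roles": ["input", "output"], "via": [10, 12]},
    "4": {"roles": ["catalyst", "output"], "via": [10, 12]}
  },
  "chains_to_signalling_complex": [[10], [8, 10]]
}
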