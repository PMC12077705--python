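# Default term lexicon for rule-based progression detection in brain-MRI
# radiology reports.  This is a RECONSTRUCTION assembled from RANO response
# language plus terms frequent in neuro-oncology surveillance reports
# (enhancement growth, recurrence, stability phrasing); edit to taste —
# document-level results depend directly on it.
#
# Stems are matched by prefix against lowercased tokens ("increas" matches
# increased / increasing / increase).  Triggers are whole-token phrases with
# a directional, sentence-bounded scope; scope is cut at terminator tokens.

progression_stems:
  - progress      # progression, progressive, progressed
  - recurr        # recurrence, recurrent
  - increas       # increased, increasing
  - enlarg        # enlarged, enlarging, enlargement
  - worsen        # worsened, worsening
  - grow          # growing, grown
  - growth
  - expand        # expanded, expanding

stability_stems:
  - stable
  - stabil        # stability, stabilized
  - unchanged
  - decreas       # decreased, decreasing
  - improv        # improved, improving
  - resolv        # resolved, resolving
  - shrink
  - regress       # regressed, regression (of disease burden)
  - reduc         # reduced, reduction

negation_triggers:
  - {phrase: "no evidence of", direction: forward}
  - {phrase: "without evidence of", direction: forward}
  - {phrase: "no evidence for", direction: forward}
  - {phrase: "no", direction: forward}
  - {phrase: "not", direction: forward}
  - {phrase: "without", direction: forward}
  - {phrase: "negative for", direction: forward}
  - {phrase: "rather than", direction: forward}
  - {phrase: "free of", direction: forward}
  # expanded no-change phrasing common in surveillance reports
  - {phrase: "no interval change", direction: forward}
  - {phrase: "no significant change", direction: forward}
  - {phrase: "not seen", direction: backward}
  - {phrase: "not identified", direction: backward}
  - {phrase: "is absent", direction: backward}
  - {phrase: "ruled out", direction: backward}

historical_triggers:
  - {phrase: "history of", direction: forward}
  - {phrase: "previously", direction: bidirectional}
  - {phrase: "previously noted", direction: forward}
  - {phrase: "prior", direction: forward}
  - {phrase: "previous", direction: forward}
  - {phrase: "known", direction: forward}
  - {phrase: "again seen", direction: backward}

hypothetical_triggers:
  - {phrase: "if", direction: forward}
  - {phrase: "possible", direction: forward}
  - {phrase: "possibly", direction: forward}
  - {phrase: "may represent", direction: forward}
  - {phrase: "could represent", direction: forward}
  - {phrase: "question of", direction: forward}
  - {phrase: "differential includes", direction: forward}
  - {phrase: "versus", direction: bidirectional}

family_triggers:
  - {phrase: "family history of", direction: forward}
  - {phrase: "mother", direction: forward}
  - {phrase: "father", direction: forward}
  - {phrase: "sibling", direction: forward}

surgical_triggers:
  - {phrase: "postoperative", direction: bidirectional}
  - {phrase: "post-operative", direction: bidirectional}
  - {phrase: "postsurgical", direction: bidirectional}
  - {phrase: "post-surgical", direction: bidirectional}
  - {phrase: "resection cavity", direction: bidirectional}
  - {phrase: "surgical cavity", direction: bidirectional}
  - {phrase: "surgical", direction: bidirectional}
  - {phrase: "operative bed", direction: bidirectional}
  - {phrase: "craniotomy", direction: bidirectional}

terminators:
  - but
  - however
  - although
  - though
  - except
  - aside
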