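# False-positive filter for drug/therapy NER output.
# A mention is removed iff one of these patterns matches its FULL surface.
# The first rule is the comparison-expression rule: a letter-initial token
# containing <, >, =, <=, >=, or the one-character forms of <= / >=,
# followed by a numeric sequence (e.g. "P≤0.001", "IC50=20").
- rule_id: comparison-expression
  pattern: "[A-Za-z][A-Za-z0-9-]*(?:<=|>=|[<>=≤≥])[0-9][0-9.]*%?"
  description: letter-initial token with a comparison operator and numeric tail
- rule_id: bare-number
  pattern: "[0-9][0-9.,]*"
  description: plain numbers
- rule_id: percentage
  pattern: "[0-9][0-9.]*\\s?%"
  description: percentages
- rule_id: p-value
  pattern: "(?i)p\\s*[<>=≤≥]?\\s*[0-9.]+"
  description: significance statements
- rule_id: numeric-range
  pattern: "[0-9.]+\\s*[-–]\\s*[0-9.]+"
  description: numeric ranges
- rule_id: dose-unit
  pattern: "(?i)[0-9.]+\\s*(?:mg|g|kg|ml|µg|ug|ng|nm|µm|um|mm)(?:/(?:kg|day|m2|ml))?"
  description: dose expressions with units
- rule_id: inhibitor
  pattern: "(?i)inhibitors?"
- rule_id: agonist
  pattern: "(?i)agonists?"
- rule_id: antagonist
  pattern: "(?i)antagonists?"
- rule_id: receptor
  pattern: "(?i)receptors?"
- rule_id: kinase
  pattern: "(?i)kinases?"
- rule_id: protein
  pattern: "(?i)proteins?"
- rule_id: gene
  pattern: "(?i)genes?"
- rule_id: pathway
  pattern: "(?i)pathways?"
- rule_id: tumor
  pattern: "(?i)tumou?rs?"
- rule_id: cancer
  pattern: "(?i)cancers?"
- rule_id: patient
  pattern: "(?i)patients?"
- rule_id: cell
  pattern: "(?i)cells?"
- rule_id: dose-word
  pattern: "(?i)dos(?:e|es|age|ages|ing)"
- rule_id: trial
  pattern: "(?i)trials?"
- rule_id: study
  pattern: "(?i)stud(?:y|ies)"
- rule_id: group
  pattern: "(?i)groups?"
- rule_id: survival
  pattern: "(?i)survival"
- rule_id: response
  pattern: "(?i)responses?"
- rule_id: placebo
  pattern: "(?i)placebo"
- rule_id: treatment
  pattern: "(?i)treatments?"
- rule_id: significance-word
  pattern: "(?i)significant(?:ly)?"
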