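# Detector mappings for the 15 autoimmune comorbidities of celiac disease,
# plus the index disease itself.  ICD-10 patterns carry descendant (*) and
# OR (|) semantics; ATC entries are prefixes; term patterns are regexes
# applied to accent-folded, case-insensitive text.
#
# The term catalog is a reconstruction from disease names and common
# French/English synonyms (the original review catalog is not published);
# treat it as a starting point, not a validated lexicon.
index:
  dui: D002446
  name: Celiac Disease
  icd: ["K90*"]
  terms:
    - {pattern: '\bceliac\s+disease\b', label: celiac disease}
    - {pattern: '\bc(o)?eliaque\b', label: coeliaque}
    - {pattern: '\bcoeliac\b', label: coeliac}
diseases:
  - dui: D003922
    name: Diabetes Mellitus, Type 1
    icd: ["E10*"]
    atc: ["A10A"]
    terms:
      - {pattern: '\bdiab\w+\b', label: diabetes}
  - dui: D003874
    name: Dermatitis Herpetiformis
    icd: ["L130"]
    terms:
      - {pattern: '\bdermatit\w+\s+herpetiform\w+\b', label: dermatitis herpetiformis}
      - {pattern: '\bduhring\b', label: duhring}
  - dui: D013967
    name: Thyroiditis, Autoimmune
    icd: ["E063"]
    atc: ["H03AA"]
    terms:
      - {pattern: '\bthyroidit\w+\b', label: thyroiditis, fuzzy: true}
      - {pattern: '\bhashimoto\b', label: hashimoto}
  - dui: D001172
    name: Arthritis, Rheumatoid
    icd: ["M069*"]
    terms:
      - {pattern: '\bpolyarthrit\w+\b', label: polyarthritis}
      - {pattern: '\brheumatoid\s+arthrit\w+\b', label: rheumatoid arthritis}
  - dui: D008180
    name: Lupus Erythematosus, Systemic
    icd: ["M32*"]
    terms:
      - {pattern: '\blupus\b', label: lupus}
  - dui: D009103
    name: Multiple Sclerosis
    icd: ["G35"]
    terms:
      - {pattern: '\bscleros\w+\s+en\s+plaques?\b', label: sclerose en plaques}
      - {pattern: '\bmultiple\s+sclerosis\b', label: multiple sclerosis}
  - dui: D012859
    name: Sjogren's Syndrome
    icd: ["M350"]
    terms:
      - {pattern: '\bsjogren\w*\b', label: sjogren}
      - {pattern: '\bgougerot\b', label: gougerot}
  - dui: D000224
    name: Addison Disease
    icd: ["E271|E272"]
    terms:
      - {pattern: '\baddison\w*\b', label: addison}
  - dui: D001171
    name: Arthritis, Juvenile
    icd: ["M089*"]
    terms:
      - {pattern: '\barthrite\s+juvenile\b', label: arthrite juvenile}
      - {pattern: '\bjuvenile\s+(idiopathic\s+)?arthrit\w+\b', label: juvenile arthritis}
  - dui: D019693
    name: Hepatitis, Autoimmune
    icd: ["K754"]
    terms:
      - {pattern: '\bhepatit\w+\s+auto-?immune?\b', label: hepatite auto-immune}
      - {pattern: '\bautoimmune\s+hepatitis\b', label: autoimmune hepatitis}
  - dui: D006111
    name: Graves' Disease
    icd: ["E050|E05*"]
    terms:
      - {pattern: '\bbasedow\b', label: basedow}
      - {pattern: '\bgraves\b', label: graves}
  - dui: D005922
    name: Glomerulonephritis, IGA
    icd: ["N0330|N0170"]
    terms:
      - {pattern: '\bmaladie\s+de\s+berger\b', label: maladie de berger}
      - {pattern: '\biga\s+nephropathy\b', label: iga nephropathy}
  - dui: D009157
    name: Myasthenia Gravis
    icd: ["G700"]
    terms:
      - {pattern: '\bmyastheni\w+\b', label: myasthenia}
  - dui: D016884
    name: Polyendocrinopathies, Autoimmune
    icd: ["E31*"]
    terms:
      - {pattern: '\bpolyendocrinopath\w+\b', label: polyendocrinopathy}
  - dui: D016736
    name: Antiphospholipid Syndrome
    icd: ["D686*"]
    terms:
      - {pattern: '\bantiphospholipid\w*\b', label: antiphospholipid}
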