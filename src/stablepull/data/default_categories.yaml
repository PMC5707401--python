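# Default RNA / Ubiquitin categorization scheme.
#
# This is a documented stand-in: a small set of GO term IDs covering
# posttranscriptional processes and the ubiquitin system.  Matching is
# by ancestor closure, so annotating any descendant of a listed term
# assigns the category.  Replace with your own curated lists via
# --categories / the `categories` config key.
categories:
  RNA:
    - "GO:0003723"   # RNA binding
    - "GO:0016070"   # RNA metabolic process
    - "GO:0006396"   # RNA processing
    - "GO:0000398"   # mRNA splicing, via spliceosome
    - "GO:0006412"   # translation
    - "GO:0010467"   # gene expression
    - "GO:0003735"   # structural constituent of ribosome
  Ubiquitin:
    - "GO:0016567"   # protein ubiquitination
    - "GO:0006511"   # ubiquitin-dependent protein catabolic process
    - "GO:0004842"   # ubiquitin-protein transferase activity
    - "GO:0061630"   # ubiquitin protein ligase activity
    - "GO:0043130"   # ubiquitin binding
    - "GO:0000502"   # proteasome complex
precedence: [RNA, Ubiquitin]
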