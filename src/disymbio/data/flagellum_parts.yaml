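# Default assignment of flagellar genes to structural parts, from the
# standard enterobacterial flagellar regulon. User-overridable: any map of
# gene -> {basal_body, hook, filament, export, regulation} is accepted.
parts:
  basal_body: [flgB, flgC, flgF, flgG, flgH, flgI, fliE, fliF, fliG, fliM, fliN]
  hook: [flgD, flgE, flgK]
  filament: [fliC, fliD, flgL]
  export: [flhA, flhB, fliH, fliI, fliP, fliQ, fliR]
  regulation: [flhC, flhD, fliA, flgM]
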