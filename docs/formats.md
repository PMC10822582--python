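# File formats

## JSON interchange (frozen)

One document is one JSON object; a corpus file is JSON Lines (one object
per line, extension `.jsonl`). All character offsets are 0-based
half-open `[start, end)` into `text`.

```json
{
  "doc_id": "pmid123",
  "text": "Knockdown of KRAS induced apoptosis in HeLa cells.",
  "mentions": [
    {
      "id": "t0",
      "category": "PerturbingAction",
      "assertion": "RNAi/knockdown",
      "start": 0,
      "end": 17,
      "surface": "Knockdown of KRAS"
    }
  ],
  "links": [
    {
      "id": "l0",
      "members": {
        "PerturbingAction": "t0",
        "Effect": "t1",
        "Phenotype": "t2",
        "Context": "t3"
      }
    }
  ]
}
```

Required document keys: `doc_id`, `text`, `mentions`, `links`.
Required mention keys: `id`, `category`, `assertion`, `start`, `end`,
`surface`. `surface` must equal `text[start:end]`. Links carry exactly
one member per category; member values are mention ids in the same
document. Readers validate on load and raise naming the offending key,
tag or id.

## Standoff XML

The annotation-tool style: a `TEXT` element with the raw abstract (as
CDATA), then a `TAGS` element holding extent tags named after their
category and `LINK` tags.

```xml
<FunctionalGenomicsTask>
  <TEXT><![CDATA[Knockdown of KRAS induced apoptosis in HeLa cells.]]></TEXT>
  <TAGS>
    <PerturbingAction id="t0" spans="0~17" text="Knockdown of KRAS"
                      assertion="RNAi/knockdown"/>
    <Effect id="t1" spans="18~25" text="induced" assertion="positive"/>
    <Phenotype id="t2" spans="26~35" text="apoptosis" assertion="apoptosis"/>
    <Context id="t3" spans="39~49" text="HeLa cells" assertion="cells"/>
    <LINK id="l0" PerturbingActionID="t0" EffectID="t1"
          PhenotypeID="t2" ContextID="t3"/>
  </TAGS>
</FunctionalGenomicsTask>
```

`spans="start~end"` uses the same 0-based half-open convention as the
in-memory representation — the reader performs no offset arithmetic and
re-checks `text[start:end]` against the `text` attribute. Comma-
separated (discontinuous) spans are rejected: the schema marks
contiguous phrases only. Category element names are matched
case-insensitively and with `_`/`-` variants (`Perturbing_action` etc.);
the assertion may be carried in an `assertion`, `label` or `type`
attribute.

## Gene mention TSV (case-study input)

Tab-separated, one externally produced gene mention per line:

```
doc_id<TAB>start<TAB>end<TAB>symbol
```
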