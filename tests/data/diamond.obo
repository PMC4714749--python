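format-version: 1.2
ontology: synthetic

[Term]
id: GO:0000001
name: root
namespace: synthetic_function

[Term]
id: GO:0000002
name: left parent
namespace: synthetic_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: right parent
namespace: synthetic_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: child
namespace: synthetic_function
is_a: GO:0000002 ! left parent
is_a: GO:0000003 ! right parent
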