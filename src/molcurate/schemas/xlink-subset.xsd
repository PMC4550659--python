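<?xml version="1.0" encoding="UTF-8"?>
<!-- Minimal xlink attribute declarations used by the METS profile below. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://www.w3.org/1999/xlink">
  <xs:attribute name="href" type="xs:anyURI"/>
  <xs:attribute name="title" type="xs:string"/>
  <xs:attribute name="type" type="xs:string"/>
</xs:schema>
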