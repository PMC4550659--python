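<?xml version="1.0" encoding="UTF-8"?>
<!-- Subset of the DSpace intermediate metadata (DIM) format: a flat list of
     qualified Dublin-Core-style fields. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://www.dspace.org/xmlns/dspace/dim"
           xmlns:dim="http://www.dspace.org/xmlns/dspace/dim"
           elementFormDefault="qualified">
  <xs:element name="dim">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="dim:field" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
  <xs:element name="field">
    <xs:complexType>
      <xs:simpleContent>
        <xs:extension base="xs:string">
          <xs:attribute name="mdschema" type="xs:string" use="required"/>
          <xs:attribute name="element" type="xs:string" use="required"/>
          <xs:attribute name="qualifier" type="xs:string"/>
          <xs:attribute name="authority" type="xs:string"/>
        </xs:extension>
      </xs:simpleContent>
    </xs:complexType>
  </xs:element>
</xs:schema>
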