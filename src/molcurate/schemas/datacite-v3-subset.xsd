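<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset profile of the DataCite Metadata Schema 3 (kernel-3) covering the
  elements this toolkit emits: the mandatory kernel (identifier, creators,
  titles, publisher, publicationYear) plus alternateIdentifiers and the
  relatedIdentifiers that carry the HasMetadata relation type introduced in
  schema version 3.0.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://datacite.org/schema/kernel-3"
           xmlns:dc="http://datacite.org/schema/kernel-3"
           elementFormDefault="qualified">

  <xs:element name="resource">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="identifier">
          <xs:complexType>
            <xs:simpleContent>
              <xs:extension base="xs:string">
                <xs:attribute name="identifierType" type="xs:string" use="required"/>
              </xs:extension>
            </xs:simpleContent>
          </xs:complexType>
        </xs:element>
        <xs:element name="creators">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="creator" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="creatorName" type="xs:string"/>
                    <xs:element name="nameIdentifier" minOccurs="0">
                      <xs:complexType>
                        <xs:simpleContent>
                          <xs:extension base="xs:string">
                            <xs:attribute name="schemeURI" type="xs:anyURI"/>
                            <xs:attribute name="nameIdentifierScheme" type="xs:string" use="required"/>
                          </xs:extension>
                        </xs:simpleContent>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="titles">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="title" type="xs:string" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="publisher" type="xs:string"/>
        <xs:element name="publicationYear">
          <xs:simpleType>
            <xs:restriction base="xs:string">
              <xs:pattern value="[\d]{4}"/>
            </xs:restriction>
          </xs:simpleType>
        </xs:element>
        <xs:element name="alternateIdentifiers" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="alternateIdentifier" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="alternateIdentifierType" type="xs:string" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="relatedIdentifiers" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="relatedIdentifier" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="relatedIdentifierType" type="xs:string" use="required"/>
                      <xs:attribute name="relationType" type="xs:string" use="required"/>
                      <xs:attribute name="relatedMetadataScheme" type="xs:string"/>
                      <xs:attribute name="schemeURI" type="xs:anyURI"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
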